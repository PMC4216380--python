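"""FASTX-style quality control of paired-end Illumina reads.

Implements the trimming/filtering/collapsing semantics of the FASTX toolkit
(fastq_quality_trimmer, fastq_quality_filter, fastx_collapser): bases are
trimmed from the 3' end while the terminal quality falls below a threshold
``t``, reads shorter than ``l`` after trimming are discarded, and a read is
kept only if at least ``p`` percent of its bases have quality >= ``q``.
A Phred score Q corresponds to an error probability of 10^(-Q/10), so q30
means 99.9% base-call accuracy and q20 means 99%.

Two pipeline modes mirror the two pre-assembly routes: ``combined_single``
pools both mates, trims/filters/collapses them as single reads;
``per_mate_paired`` trims and filters each mate and keeps a pair only when
both mates survive.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Literal, Sequence

PHRED33_OFFSET = 33


@dataclass(frozen=True)
class QualityRead:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: Literal["first", "second", "unpaired"] = "unpaired"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities lengths differ")
        if any(q < 0 or q > 60 for q in self.qualities):
            raise ValueError("Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCParams:
    """FASTX QC parameter set: end-trim threshold t, min length l,
    filter threshold q, and the percentage p of bases that must reach q."""

    t: int = 30
    l: int = 50
    q: int = 30
    p: float = 90.0

    def __post_init__(self) -> None:
        if not (0 <= self.t <= 60 and 0 <= self.q <= 60):
            raise ValueError("quality thresholds must lie in [0, 60]")
        if self.l < 1:
            raise ValueError("minimum length must be >= 1")
        if not (0 < self.p <= 100):
            raise ValueError("p must lie in (0, 100]")


@dataclass(frozen=True)
class QCReport:
    raw_count: int
    trimmed_discarded: int
    filter_discarded: int
    clean_count: int

    @property
    def percent_removed(self) -> float:
        if self.raw_count == 0:
            return 0.0
        return (self.trimmed_discarded + self.filter_discarded) / self.raw_count

    def to_dict(self) -> dict:
        d = {
            "raw_count": self.raw_count,
            "trimmed_discarded": self.trimmed_discarded,
            "filter_discarded": self.filter_discarded,
            "clean_count": self.clean_count,
            "percent_removed": self.percent_removed,
        }
        return d


def phred_error_probability(q: int) -> float:
    """Probability of an incorrect base call at Phred score ``q``.

    Q30 -> 0.001 (99.9% accuracy); Q20 -> 0.01 (99% accuracy).
    """
    if q < 0:
        raise ValueError("Phred score must be non-negative")
    return 10.0 ** (-q / 10.0)


def trim_read(read: QualityRead, t: int, l: int) -> QualityRead | None:
    """Trim low-quality bases from the 3' end; discard short survivors.

    Bases are removed from the 3' end while the terminal base quality is
    below ``t`` (fastq_quality_trimmer behaviour).  Returns None when the
    surviving prefix is shorter than ``l``.
    """
    end = len(read)
    quals = read.qualities
    while end > 0 and quals[end - 1] < t:
        end -= 1
    if end < l:
        return None
    if end == len(read):
        return read
    return replace(read, sequence=read.sequence[:end], qualities=quals[:end])


def filter_read(read: QualityRead, q: int, p: float) -> bool:
    """Keep a read iff >= p% of its bases have quality >= q.

    N bases count as quality-failing regardless of their score; the p
    threshold is inclusive.  Zero-length reads are discarded.
    """
    n = len(read)
    if n == 0:
        return False
    good = sum(
        1
        for base, qual in zip(read.sequence, read.qualities)
        if qual >= q and base != "N"
    )
    return good * 100.0 >= p * n


def collapse_identical(sequences: Iterable[str]) -> list[tuple[str, int]]:
    """Collapse identical sequences into (sequence, multiplicity) records.

    Output is sorted by descending multiplicity, ties broken lexicographically
    by sequence (fastx_collapser semantics); multiplicities sum to the input
    count.
    """
    counts = Counter(sequences)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _qc_single(
    reads: Sequence[QualityRead], params: QCParams
) -> tuple[list[QualityRead], int, int]:
    clean: list[QualityRead] = []
    n_trim = n_filt = 0
    for read in reads:
        trimmed = trim_read(read, params.t, params.l)
        if trimmed is None:
            n_trim += 1
        elif not filter_read(trimmed, params.q, params.p):
            n_filt += 1
        else:
            clean.append(trimmed)
    return clean, n_trim, n_filt


def qc_pipeline(
    reads1: Sequence[QualityRead],
    reads2: Sequence[QualityRead] | None,
    params: QCParams,
    mode: Literal["combined_single", "per_mate_paired"] = "per_mate_paired",
):
    """Run trim -> filter (-> collapse) over a read set.

    combined_single
        Mates are pooled and processed as single reads; identical survivors
        are collapsed.  Returns (clean_reads, collapsed, report).
    per_mate_paired
        Each mate is trimmed and filtered; a pair is retained intact only
        when both mates survive (orphans drop the whole pair).  Returns
        (clean_pairs, None, report).  When one mate fails, both reads of
        the pair are charged to the stage that caused the drop, keeping
        raw = clean + trimmed_discarded + filter_discarded exact.
    """
    if mode == "combined_single":
        pool = list(reads1) + (list(reads2) if reads2 else [])
        clean, n_trim, n_filt = _qc_single(pool, params)
        report = QCReport(len(pool), n_trim, n_filt, len(clean))
        collapsed = collapse_identical(r.sequence for r in clean)
        return clean, collapsed, report

    if mode != "per_mate_paired":
        raise ValueError(f"unknown mode: {mode!r}")
    if reads2 is None or len(reads1) != len(reads2):
        raise ValueError("per_mate_paired mode needs equal-length mate lists")

    pairs: list[tuple[QualityRead, QualityRead]] = []
    n_trim = n_filt = 0
    for r1, r2 in zip(reads1, reads2):
        t1 = trim_read(r1, params.t, params.l)
        t2 = trim_read(r2, params.t, params.l)
        if t1 is None or t2 is None:
            n_trim += 2
            continue
        if not filter_read(t1, params.q, params.p) or not filter_read(
            t2, params.q, params.p
        ):
            n_filt += 2
            continue
        pairs.append((t1, t2))
    raw = len(reads1) + len(reads2)
    report = QCReport(raw, n_trim, n_filt, 2 * len(pairs))
    return pairs, None, report


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O (4-line FASTQ records, Phred+33 by default)


def read_fastq(path, mate: str = "unpaired", offset: int = PHRED33_OFFSET) -> list[QualityRead]:
    reads = []
    with open(path) as fh:
        for rec in _iter_fastq(fh):
            rid, seq, qual = rec
            reads.append(
                QualityRead(rid, seq, tuple(ord(c) - offset for c in qual), mate)
            )
    return reads


def _iter_fastq(fh) -> Iterator[tuple[str, str, str]]:
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header: {header!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not plus.startswith("+") or len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record at {header!r}")
        yield header[1:].split()[0], seq, qual


def write_fastq(reads: Iterable[QualityRead], path, offset: int = PHRED33_OFFSET) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + offset) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_collapsed_fasta(collapsed: Sequence[tuple[str, int]], path) -> None:
    """Write collapsed sequences as FASTA with '<rank>-<count>' headers."""
    with open(path, "w") as fh:
        for rank, (seq, count) in enumerate(collapsed, start=1):
            fh.write(f">{rank}-{count}\n{seq}\n")


def write_report(report: QCReport, json_path=None, tsv_path=None) -> None:
    d = report.to_dict()
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(d, fh, indent=2)
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("\t".join(d.keys()) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")
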