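"""Core-transcript quality assessment of de novo assemblies.

N50 and contig counts can mislead; a more direct gauge of assembly quality
is whether a suite of control transcripts spanning the expression range —
from the highly expressed LEA down to a low-abundance protein kinase — is
recovered.  Per core gene the suite reports (i) the percentage of the full
protein query covered by the best translated-search hit and (ii) the
average read coverage of the identified transcript, defined as the sum of
aligned read bases divided by the reference length.  Presence of the two
lowest-tier genes (CP-1, PK) indicates that transcripts of similar
abundance to the target family would have been captured.

Read mapping uses edit costs mismatch 2 / insertion 3 / deletion 3, with a
read accepted only when at least 80% of its length aligns (length fraction)
at >= 80% identity over the aligned part (similarity fraction); both
thresholds inclusive.  A fast unit-cost candidate scan (edlib) locates the
best placement, which is then rescored as a local alignment under the
stated costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
from Bio import Align

from .assembler import Contig, reverse_complement
from .translated_search import AlignmentHit, best_hit, tblastn_like_search


@dataclass(frozen=True)
class MappingParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.8
    similarity_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not (0 < f <= 1):
                raise ValueError("fractions must lie in (0, 1]")


@dataclass(frozen=True)
class CoreGene:
    name: str
    query_protein: str
    expected_tier: float  # average coverage anchor; orders high -> low


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    reference_id: str
    ref_start: int  # 0-based
    aligned_base_count: int  # reference-consuming matched+mismatched bases
    matches: int
    cost: int
    orientation: int  # +1 forward, -1 reverse
    cigar: str


@dataclass(frozen=True)
class QCRow:
    gene: str
    query_coverage_percent: int
    average_coverage: float


def _make_dna_aligner(params: MappingParams) -> Align.PairwiseAligner:
    # local alignment mirroring the edit costs: match +1, mismatch -(cost),
    # gaps -(cost); positive match keeps the local optimum well-defined
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -float(params.mismatch_cost)
    a.open_gap_score = -float(params.insertion_cost)
    a.extend_gap_score = -float(params.insertion_cost)
    return a


def map_reads(
    reads: Iterable,
    reference: str,
    params: MappingParams = MappingParams(),
    reference_id: str = "reference",
) -> list[ReadAlignment]:
    """Best-placement mapping of reads against one reference sequence.

    Each read is screened on both strands with a banded unit-cost scan; the
    better strand's best placement is rescored as a local alignment and
    accepted iff aligned read fraction >= length_fraction and identity over
    the aligned columns >= similarity_fraction (ties prefer the forward
    strand, then the leftmost placement).  Unmapped reads are absent.
    """
    if not reference:
        raise ValueError("empty reference")
    aligner = _make_dna_aligner(params)
    out: list[ReadAlignment] = []
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        rid = getattr(read, "read_id", f"read_{len(out)}")
        n = len(seq)
        max_dist = max(1, int(n * (1 - params.similarity_fraction) + n * (1 - params.length_fraction)) + 2)
        best = None  # (dist, -strand, candidate seq, strand)
        for strand, s in ((1, seq), (-1, reverse_complement(seq))):
            r = edlib.align(s, reference, mode="HW", task="distance", k=max_dist)
            d = r["editDistance"]
            if d != -1 and (best is None or d < best[0]):
                best = (d, s, strand)
        if best is None:
            continue
        _, s, strand = best
        aln = _best_local(aligner, s, reference)
        if aln is None:
            continue
        matches, mismatches, ref_consumed, read_consumed, ref_start, cigar = aln
        aligned_cols = matches + mismatches
        if read_consumed < params.length_fraction * n:
            continue
        if aligned_cols == 0 or matches < params.similarity_fraction * aligned_cols:
            continue
        cost = (
            mismatches * params.mismatch_cost
            + (read_consumed - aligned_cols) * params.insertion_cost
            + (ref_consumed - aligned_cols) * params.deletion_cost
        )
        out.append(
            ReadAlignment(
                rid, reference_id, ref_start, ref_consumed, matches, cost, strand, cigar
            )
        )
    return out


def _best_local(aligner, read: str, reference: str):
    try:
        alignment = next(iter(aligner.align(reference, read)))
    except (StopIteration, OverflowError):
        return None
    ref_blocks, read_blocks = alignment.aligned
    if len(ref_blocks) == 0:
        return None
    matches = mismatches = 0
    cigar_parts: list[str] = []
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if prev_r is not None:
            if rs > prev_r:
                cigar_parts.append(f"{rs - prev_r}D")
            if qs > prev_q:
                cigar_parts.append(f"{qs - prev_q}I")
        cigar_parts.append(f"{re_ - rs}M")
        for a, b in zip(reference[rs:re_], read[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_r, prev_q = re_, qe
    ref_consumed = ref_blocks[-1][1] - ref_blocks[0][0]
    read_consumed = read_blocks[-1][1] - read_blocks[0][0]
    return matches, mismatches, ref_consumed, read_consumed, int(ref_blocks[0][0]), "".join(cigar_parts)


def average_coverage(alignments: Sequence[ReadAlignment], reference_length: int) -> float:
    """Sum of aligned read bases divided by the reference length."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    return sum(a.aligned_base_count for a in alignments) / reference_length


def query_coverage_percent(hit: Optional[AlignmentHit], query_length_aa: int) -> int:
    """Aligned query residues as an integer percentage of the full query."""
    if hit is None:
        return 0
    covered = hit.query_span[1] - hit.query_span[0] + 1
    return int(round(100.0 * covered / query_length_aa))


def _round_coverage(x: float) -> float:
    return float(int(round(x))) if x >= 100 else round(x, 1)


def core_suite_report(
    contigs: Sequence[Contig],
    reads: Sequence,
    core_genes: Sequence[CoreGene],
    params: MappingParams = MappingParams(),
    min_score: float = 60.0,
) -> tuple[list[QCRow], bool]:
    """Per core gene: best translated hit -> query coverage %; reads mapped to
    the identified transcript -> average coverage.  The verdict is positive
    ('low-abundance-capable') iff both CP-1 and PK are at least partially
    recovered."""
    rows: list[QCRow] = []
    by_id = {c.contig_id: c for c in contigs}
    for gene in core_genes:
        hit = best_hit(tblastn_like_search(gene.query_protein, contigs, min_score=min_score))
        qcov = query_coverage_percent(hit, len(gene.query_protein))
        avg = 0.0
        if hit is not None:
            ref = by_id[hit.contig_id].sequence
            alns = map_reads(reads, ref, params, reference_id=hit.contig_id)
            avg = average_coverage(alns, len(ref))
        rows.append(QCRow(gene.name, qcov, _round_coverage(avg)))
    found = {r.gene: r.query_coverage_percent for r in rows}
    verdict = found.get("CP-1", 0) > 0 and found.get("PK", 0) > 0
    return rows, verdict


def write_qc_tsv(rows: Iterable[QCRow], path, verdict: Optional[bool] = None) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tquery_coverage_percent\taverage_coverage\n")
        for r in rows:
            fh.write(f"{r.gene}\t{r.query_coverage_percent}\t{r.average_coverage}\n")
        if verdict is not None:
            fh.write(f"# low-abundance-capable: {'yes' if verdict else 'no'}\n")


def write_sam(
    alignments: Iterable[ReadAlignment],
    reference_id: str,
    reference_length: int,
    path,
) -> None:
    """Minimal SAM export (QNAME/FLAG/RNAME/POS/CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_id}\tLN:{reference_length}\n")
        for a in alignments:
            flag = 16 if a.orientation == -1 else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.reference_id}\t{a.ref_start + 1}\t255\t"
                f"{a.cigar}\t*\t0\t0\t*\t*\n"
            )
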