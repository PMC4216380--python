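"""tBLASTn-like screening of assembled contigs with a protein query.

Each contig is translated in all six reading frames and locally aligned to
the query protein under a BLOSUM62 scoring scheme with affine gaps
(existence 11, extension 1, the conventional tBLASTn defaults).  In-frame
stop codons are rendered '*' and score a hard -10 against everything, so
optimal local alignments effectively do not cross a stop — precursor ORFs
are contiguous.  The contig's score is the maximum over its six frames;
hits at or above a minimum score are ranked by descending score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .assembler import Contig, reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)

#: default minimum reported score, in substitution-matrix units
DEFAULT_MIN_SCORE = 40.0
STOP_SCORE = -10.0


def _scoring_matrix():
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    alphabet = mat.alphabet
    star = alphabet.index("*")
    arr[star, :] = STOP_SCORE
    arr[:, star] = STOP_SCORE
    return substitution_matrices.Array(alphabet=alphabet, data=arr)


_MATRIX = _scoring_matrix()
_ALPHABET = set(_MATRIX.alphabet)


def _make_aligner(mode: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _MATRIX
    # BLAST convention: a gap of length g costs gap_open + g*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if mode == "global":
        # end-gap-free (semi-global) semantics for region projection
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    contig_id: str
    frame: int
    score: float
    percent_identity: float
    query_span: tuple[int, int]  # 1-based inclusive, on the query protein
    subject_span: tuple[int, int]  # 1-based inclusive, on the translated frame


def six_frame_translate(sequence: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; stops as '*'; codons containing N become 'X';
    trailing partial codons are dropped.  Frames -1..-3 read the reverse
    complement.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence contains non-IUPAC characters (allowed: ACGTN)")
    out: dict[int, str] = {}
    rc = reverse_complement(seq)
    for frame in FRAMES:
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        trimmed = s[off : off + 3 * ((len(s) - off) // 3)]
        out[frame] = str(Seq(trimmed).translate())
    return out


def _alignment_stats(alignment, query: str, subject: str):
    """(identity %, query span, subject span) from a Bio.Align alignment."""
    qa, sa = alignment.aligned  # blocks on target (query) and query (subject)
    if len(qa) == 0:
        return 0.0, (0, 0), (0, 0)
    matches = 0
    cols = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    # gap columns inside the local alignment also count toward identity's denominator
    q_span = (qa[0][0] + 1, qa[-1][1])
    s_span = (sa[0][0] + 1, sa[-1][1])
    q_len = qa[-1][1] - qa[0][0]
    s_len = sa[-1][1] - sa[0][0]
    total_cols = cols + (q_len - cols) + (s_len - cols)
    identity = 100.0 * matches / total_cols if total_cols else 0.0
    return identity, q_span, s_span


def local_align_protein(
    query: str,
    subject: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
):
    """Best local alignment of two proteins under BLOSUM62/affine gaps.

    Returns (score, identity %, query span, subject span); spans are 1-based
    inclusive.  A score of 0 with empty spans means no positive-scoring local
    alignment exists.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    for s in (query, subject):
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(f"unknown residue(s): {sorted(bad)}")
    aligner = _make_aligner("local", gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0.0, (0, 0), (0, 0)
    alignment = next(iter(aligner.align(query, subject)))
    identity, q_span, s_span = _alignment_stats(alignment, query, subject)
    return float(score), identity, q_span, s_span


def global_align_protein(query: str, subject: str):
    """End-gap-free global alignment; returns the Bio.Align alignment object."""
    aligner = _make_aligner("global")
    return next(iter(aligner.align(query, subject)))


def tblastn_like_search(
    query: str,
    contigs: Sequence[Contig],
    min_score: float = DEFAULT_MIN_SCORE,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Score each contig as the max over its six translated frames.

    Hits with score >= min_score are returned sorted by descending score,
    ties broken by contig id (numeric-aware).
    """
    hits: list[AlignmentHit] = []
    for contig in contigs:
        if len(contig.sequence) < 3:
            continue
        best: Optional[AlignmentHit] = None
        for frame, protein in six_frame_translate(contig.sequence).items():
            if not protein:
                continue
            score, ident, q_span, s_span = local_align_protein(query, protein)
            if score <= 0:
                continue
            if best is None or score > best.score:
                best = AlignmentHit(
                    query_id, contig.contig_id, frame, score, round(ident, 2), q_span, s_span
                )
        if best is not None and best.score >= min_score:
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, _natural_key(h.contig_id)))
    return hits


def _natural_key(s: str):
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s))


def best_hit(hits: Sequence[AlignmentHit]) -> Optional[AlignmentHit]:
    """The maximal-score hit under the documented ordering, or None."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, _natural_key(h.contig_id)))


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """outfmt-6-like columns: query, subject, %identity, score, frame, spans."""
    with open(path, "w") as fh:
        fh.write("query\tsubject\tpident\tscore\tframe\tqstart\tqend\tsstart\tsend\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.contig_id}\t{h.percent_identity}\t{h.score}\t"
                f"{h.frame}\t{h.query_span[0]}\t{h.query_span[1]}\t"
                f"{h.subject_span[0]}\t{h.subject_span[1]}\n"
            )
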