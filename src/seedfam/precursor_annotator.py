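"""Rule-based annotation of seed-albumin precursor ORFs (PawS1 / PawL1).

Napin-type seed storage albumin precursors carry an ER signal peptide and a
spacer, then the mature chain: a small subunit (SSU, two conserved Cys) and
a large subunit (LSU, six conserved Cys) separated by a second spacer.  In
PawS1-type precursors an extra peptide (the PDP) is buried between the first
spacer and the SSU: it typically starts with Gly, ends with Asp, contains two
conserved Cys that form its disulfide, and is followed by a four-residue
tail, in most cases Gly-Leu-Asp-Asn.  PawL1 precursors share the layout but
their buried region has no Cys pair and yields no stable peptide.

Region boundaries on a candidate protein are inferred by end-gap-free global
alignment to a reference precursor of known architecture (e.g. sunflower
PawS1), then the PDP span is refined locally by the start-Gly/end-Asp/tail
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .assembler import Contig
from .translated_search import (
    AlignmentHit,
    _natural_key,
    global_align_protein,
    six_frame_translate,
    tblastn_like_search,
)

REGION_ORDER = ("er_signal", "spacer1", "pdp", "tail", "ssu", "spacer2", "lsu")

#: admissible PDP length range (residues), chosen around observed 12-22
PDP_MIN_LEN = 10
PDP_MAX_LEN = 40
#: minimum matches of the 4-residue tail to GLDN
TAIL_MIN_MATCHES = 2
TAIL_CONSENSUS = "GLDN"


@dataclass(frozen=True)
class Orf:
    contig_id: str
    frame: int
    protein: str
    nt_span: tuple[int, int]  # 1-based inclusive on the contig, forward strand
    completeness: str  # complete | missing_start | missing_stop | fragment


@dataclass
class PrecursorAnnotation:
    orf: Orf
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    pdp_sequence: str = ""
    pdp_cys_count: int = 0
    ssu_cys_count: int = 0
    lsu_cys_count: int = 0
    class_label: str = "none"
    confidence: str = "complete"  # downgraded to "partial" when regions are absent
    notes: list[str] = field(default_factory=list)

    @property
    def protein(self) -> str:
        return self.orf.protein


def find_orfs(
    contig: Contig | str,
    frame_hint: Optional[int] = None,
    min_protein_length: int = 60,
    contig_id: str = "contig",
) -> list[Orf]:
    """All maximal ORFs of at least ``min_protein_length`` residues.

    Segments between stop codons are examined per frame; an ORF runs from the
    first Met of the segment when one exists.  Completeness records whether
    the start Met and the terminating stop are both inside the contig.
    """
    if isinstance(contig, Contig):
        seq, cid = contig.sequence, contig.contig_id
    else:
        seq, cid = contig, contig_id
    frames = [frame_hint] if frame_hint else list(six_frame_translate(seq))
    translations = six_frame_translate(seq)
    n = len(seq)
    orfs: list[Orf] = []
    for frame in frames:
        protein = translations[frame]
        seg_start = 0
        segments = []
        for i, aa in enumerate(protein):
            if aa == "*":
                segments.append((seg_start, i, True))  # stop-terminated
                seg_start = i + 1
        if seg_start < len(protein):
            segments.append((seg_start, len(protein), False))
        for s, e, has_stop in segments:
            seg = protein[s:e]
            m = seg.find("M")
            if m >= 0:
                aa_start, orf_prot = s + m, seg[m:]
                completeness = "complete" if has_stop else "missing_stop"
            else:
                # Met-less segment: a 5'-truncated coding fragment; the
                # upstream stop may sit in UTR sequence carried by the contig
                aa_start, orf_prot = s, seg
                if s == 0 and has_stop:
                    completeness = "missing_start"
                else:
                    completeness = "fragment"
            if len(orf_prot) < min_protein_length:
                continue
            off = abs(frame) - 1
            nt_a = off + 3 * aa_start  # 0-based on the reading strand
            nt_b = nt_a + 3 * len(orf_prot) - 1
            if frame > 0:
                span = (nt_a + 1, nt_b + 1)
            else:
                span = (n - nt_b, n - nt_a)
            orfs.append(Orf(cid, frame, orf_prot, span, completeness))
    orfs.sort(key=lambda o: (-len(o.protein), o.frame, o.nt_span))
    return orfs


def _projection_map(alignment) -> dict[int, int]:
    """ref position -> candidate position (0-based) over aligned columns."""
    proj: dict[int, int] = {}
    ref_blocks, cand_blocks = alignment.aligned
    for (rs, re_), (cs, ce) in zip(ref_blocks, cand_blocks):
        for off in range(re_ - rs):
            proj[rs + off] = cs + off
    return proj


def delimit_regions(
    protein: str,
    reference_precursor: str,
    reference_regions: Mapping[str, tuple[int, int]],
    orf: Optional[Orf] = None,
    min_identity: float = 20.0,
) -> PrecursorAnnotation:
    """Project reference region boundaries onto a candidate protein.

    The candidate is globally aligned (end gaps free) to the reference; each
    reference region's span is carried through the alignment.  Regions whose
    residues are entirely unaligned are marked absent.  The PDP span is then
    refined by ``detect_pdp``.  Alignment identity below ``min_identity``
    percent yields class 'none' with no regions.
    """
    if orf is None:
        orf = Orf("candidate", 1, protein, (1, 3 * len(protein)), "complete")
    ann = PrecursorAnnotation(orf)
    alignment = global_align_protein(reference_precursor, protein)
    proj = _projection_map(alignment)
    matches = sum(
        1 for r, c in proj.items() if reference_precursor[r] == protein[c]
    )
    # normalise by the shorter sequence so fragments are not penalised, but
    # a tiny aligned island of an unrelated protein cannot score high
    denom = min(len(reference_precursor), len(protein))
    identity = 100.0 * matches / max(denom, 1)
    if not proj or identity < min_identity:
        ann.class_label = "none"
        ann.notes.append(f"reference identity {identity:.1f}% below threshold")
        return ann

    for name in REGION_ORDER:
        if name not in reference_regions:
            continue
        r0, r1 = reference_regions[name]
        cols = [proj[p] for p in range(r0 - 1, r1) if p in proj]
        if not cols:
            ann.notes.append(f"{name} absent")
            continue
        ann.regions[name] = (min(cols) + 1, max(cols) + 1)

    # refine the PDP + tail locally within a window around the projection
    ssu_start = ann.regions.get("ssu", (None,))[0]
    window = _pdp_window(ann.regions, len(protein))
    if window is not None:
        found = detect_pdp(protein, window, projected_ssu_start=ssu_start)
        if found is not None:
            pdp_span, tail_span, ambiguous = found
            ann.regions["pdp"] = pdp_span
            ann.regions["tail"] = tail_span
            if ambiguous:
                ann.notes.append("ambiguous PDP window; chose span abutting the SSU")
        else:
            ann.regions.pop("pdp", None)
            ann.regions.pop("tail", None)
    _fill_cys_counts(ann)
    return ann


def _pdp_window(regions: Mapping[str, tuple[int, int]], n: int, margin: int = 8):
    if "pdp" in regions:
        a, b = regions["pdp"]
    elif "spacer1" in regions and "ssu" in regions:
        a, b = regions["spacer1"][1] + 1, regions["ssu"][0] - 1
    else:
        return None
    return (max(1, a - margin), min(n, b + margin + 6))


def detect_pdp(
    protein: str,
    window: tuple[int, int],
    projected_ssu_start: Optional[int] = None,
):
    """Find the buried-peptide span inside a search window.

    A qualifying span starts with Gly, ends with Asp, is 10-40 residues long
    and is followed immediately by a 4-residue tail matching GLDN in at least
    2 of 4 positions.  Among qualifying spans the one whose end sits closest
    to the projected SSU start is chosen (ties: shortest, then leftmost).
    Returns ((pdp_start, pdp_end), (tail_start, tail_end), ambiguous) in
    1-based coordinates, or None.
    """
    w0, w1 = window
    cands = []
    for i in range(w0 - 1, w1):
        if i >= len(protein) or protein[i] != "G":
            continue
        for j in range(i + PDP_MIN_LEN - 1, min(i + PDP_MAX_LEN, w1, len(protein))):
            if protein[j] != "D":
                continue
            tail = protein[j + 1 : j + 5]
            if len(tail) < 4:
                continue
            if sum(a == b for a, b in zip(tail, TAIL_CONSENSUS)) < TAIL_MIN_MATCHES:
                continue
            cands.append((i + 1, j + 1))
    if not cands:
        return None
    target_end = projected_ssu_start - 5 if projected_ssu_start else None

    def rank(span):
        a, b = span
        closeness = abs(b - target_end) if target_end is not None else 0
        return (closeness, b - a, a)

    best = min(cands, key=rank)
    return (best, (best[1] + 1, best[1] + 4), len(cands) > 1)


def _cys_in(protein: str, span: tuple[int, int]) -> int:
    return protein[span[0] - 1 : span[1]].count("C")


def _fill_cys_counts(ann: PrecursorAnnotation) -> None:
    p = ann.protein
    if "pdp" in ann.regions:
        ann.pdp_sequence = p[ann.regions["pdp"][0] - 1 : ann.regions["pdp"][1]]
        ann.pdp_cys_count = ann.pdp_sequence.count("C")
    if "ssu" in ann.regions:
        ann.ssu_cys_count = _cys_in(p, ann.regions["ssu"])
    if "lsu" in ann.regions:
        ann.lsu_cys_count = _cys_in(p, ann.regions["lsu"])


def classify_precursor(ann: PrecursorAnnotation) -> str:
    """Apply the architecture rules to an annotated precursor.

    PawS1: PDP present with exactly two Cys, SSU with two and LSU with six
    conserved Cys.  PawL1: as PawS1 but the PDP has no Cys.  albumin_only:
    the albumin checks pass but no qualifying PDP exists.  Checks on absent
    regions are skipped and downgrade confidence to 'partial' instead of
    rejecting — partial transcripts are still informative.
    """
    regions = ann.regions
    partial = ann.orf.completeness != "complete" or any(
        r not in regions for r in REGION_ORDER
    )
    ssu_ok = "ssu" not in regions or ann.ssu_cys_count == 2
    lsu_ok = "lsu" not in regions or ann.lsu_cys_count == 6
    albumin_ok = ssu_ok and lsu_ok and ("ssu" in regions or "lsu" in regions)

    if "pdp" in regions and albumin_ok and ann.pdp_cys_count == 2:
        label = "PawS1"
    elif "pdp" in regions and albumin_ok and ann.pdp_cys_count == 0:
        label = "PawL1"
    elif albumin_ok:
        label = "albumin_only"
    else:
        label = "none"
    ann.class_label = label
    ann.confidence = "partial" if partial else "complete"
    return label


def mine_transcriptome(
    contigs: Sequence[Contig],
    query_protein: str,
    reference_precursor: str,
    reference_regions: Mapping[str, tuple[int, int]],
    min_score: float = 40.0,
    min_protein_length: int = 60,
) -> list[PrecursorAnnotation]:
    """Search -> ORF calling -> region delimitation -> classification.

    Annotations with identical protein sequences are reported once; output
    order is (class, contig id).
    """
    by_id = {c.contig_id: c for c in contigs}
    hits = tblastn_like_search(query_protein, contigs, min_score=min_score)
    seen: set[str] = set()
    out: list[PrecursorAnnotation] = []
    for hit in hits:
        contig = by_id[hit.contig_id]
        orfs = find_orfs(contig, frame_hint=hit.frame, min_protein_length=min_protein_length)
        if not orfs:
            continue
        # the ORF overlapping the hit's subject span, longest first
        s0, s1 = hit.subject_span
        orf = max(
            orfs,
            key=lambda o: (_frame_overlap(o, s0, s1, len(contig.sequence)), len(o.protein)),
        )
        if orf.protein in seen:
            continue
        seen.add(orf.protein)
        ann = delimit_regions(orf.protein, reference_precursor, reference_regions, orf=orf)
        classify_precursor(ann)
        out.append(ann)
    class_rank = {"PawS1": 0, "PawL1": 1, "albumin_only": 2, "none": 3}
    out.sort(key=lambda a: (class_rank[a.class_label], _natural_key(a.orf.contig_id)))
    return out


def _frame_overlap(orf: Orf, s0: int, s1: int, contig_len: int) -> int:
    """Overlap (in residues) between an ORF and a frame-local subject span."""
    off = abs(orf.frame) - 1
    if orf.frame > 0:
        a = (orf.nt_span[0] - 1 - off) // 3
    else:
        a = (contig_len - orf.nt_span[1] - off) // 3
    b = a + len(orf.protein) - 1
    return max(0, min(b, s1 - 1) - max(a, s0 - 1) + 1)


def merge_overlapping_orfs(a: str, b: str, min_overlap: int = 10) -> Optional[str]:
    """Concatenate two partial ORF proteins whose overlap is identical.

    Mirrors the manual reconstruction of a full ORF from overlapping partial
    transcripts found at different word sizes; merges only on a perfect
    overlap of at least ``min_overlap`` residues.
    """
    for x, y in ((a, b), (b, a)):
        best = None
        for olen in range(min(len(x), len(y)), min_overlap - 1, -1):
            if x[-olen:] == y[:olen]:
                best = x + y[olen:]
                break
        if best:
            return best
    return None


def write_annotation_tsv(annotations: Iterable[PrecursorAnnotation], path) -> None:
    cols = [
        "contig_id", "frame", "class", "confidence", "completeness",
        "pdp", "pdp_cys", "ssu_cys", "lsu_cys",
    ] + [f"{r}_span" for r in REGION_ORDER]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in annotations:
            spans = [
                "{}-{}".format(*a.regions[r]) if r in a.regions else "."
                for r in REGION_ORDER
            ]
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            a.orf.contig_id, a.orf.frame, a.class_label, a.confidence,
                            a.orf.completeness, a.pdp_sequence or ".",
                            a.pdp_cys_count, a.ssu_cys_count, a.lsu_cys_count,
                        ],
                    )
                )
                + "\t" + "\t".join(spans) + "\n"
            )


def region_markup(ann: PrecursorAnnotation) -> str:
    """Text rendering of the region blocks along the protein, one region
    letter per residue (S=signal, -=spacer, P=PDP, T=tail, s=SSU, L=LSU)."""
    codes = {
        "er_signal": "S", "spacer1": "-", "pdp": "P", "tail": "T",
        "ssu": "s", "spacer2": "-", "lsu": "L",
    }
    track = ["."] * len(ann.protein)
    for name, (a, b) in ann.regions.items():
        for i in range(a - 1, b):
            track[i] = codes[name]
    return ann.protein + "\n" + "".join(track)
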