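"""Seeded simulator: precursor gene families, tiered transcriptomes, reads.

Stands in for real seed RNA-seq so every pipeline stage is testable at desk
scale.  It emulates the statistical structure the method assumes:

* a family of near-identical precursor paralogs derived from one ancestor by
  nucleotide substitutions, with the buried-peptide (PDP) block evolving
  faster than the flanking albumin (a relative-rate multiplier);
* a minority of paralogs whose PDP Cys pair has been substituted away
  (PawL-type, no stable peptide);
* transcript abundance tiers spanning the observed range from very high
  (LEA-like) to below the target family, scaled down for desk runs;
* 2 x 101 paired-end reads with substitution errors and 3'-decaying Phred
  quality strings.

Every generator is deterministic under its seed.  The ancestral precursor is
built to satisfy the annotator's architecture rules exactly, and mutations
that would break a rule the truth set relies on (stop codons, gained or lost
conserved Cys, the PDP boundary Gly/Asp, the tail) are rejected and the site
left unchanged, so truth labels remain decidable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .assembler import Contig, reverse_complement
from .precursor_annotator import PrecursorAnnotation
from .read_qc import QualityRead
from .translated_search import local_align_protein

# Table of abundance-tier anchors for the six core control genes
# (name, protein length aa, average-coverage anchor), high to low.
CORE_TIERS = (
    ("LEA", 104, 174360.0),
    ("OLE", 183, 9894.0),
    ("AP", 509, 1561.0),
    ("PR", 158, 503.0),
    ("CP-1", 461, 126.0),
    ("PK", 439, 50.0),
)

#: the target family sits near average coverage 500 in the real data
FAMILY_TIER = 500.0

#: default desk scale applied to the tier anchors
DEFAULT_SCALE = 0.01

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTT", "TTC"), "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"), "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"), "W": ("TGG",), "Y": ("TAT", "TAC"),
}
_CODON_TO_AA = {c: aa for aa, cs in _CODONS.items() for c in cs}
for _stop in ("TAA", "TAG", "TGA"):
    _CODON_TO_AA[_stop] = "*"

_BASES = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """Conditions for a synthetic paralog family.

    mean_divergence is the expected substitutions/site from the ancestor;
    per-paralog divergence is drawn uniformly in [0.2, 1.8] x mean so sister
    paralogs differ in how separable they are at a given word size.  The PDP
    block mutates at pdp_rate_multiplier times the flanking rate.
    """

    n_paralogs: int = 15
    mean_divergence: float = 0.08
    pdp_rate_multiplier: float = 4.0
    pawl_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paralogs < 1:
            raise ValueError("need at least one paralog")
        if not (0 <= self.mean_divergence <= 0.5):
            raise ValueError("mean divergence must lie in [0, 0.5]")
        if self.pdp_rate_multiplier < 1:
            raise ValueError("PDP rate multiplier must be >= 1")
        if not (0 <= self.pawl_fraction <= 1):
            raise ValueError("pawl fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ReadSimSpec:
    """Illumina-like 2 x 101 paired-end read model."""

    read_length: int = 101
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    q_start: float = 37.0
    q_end: float = 35.0
    q_jitter: float = 3.0
    q_read_sd: float = 1.5  # per-read baseline shift
    bad_tail_fraction: float = 0.10  # reads whose 3' end decays much further
    bad_tail_drop: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate <= 0.05):
            raise ValueError("error rate must lie in [0, 0.05]")


@dataclass
class ParalogTruth:
    name: str
    protein: str
    cds: str
    class_label: str  # PawS1 | PawL1
    pdp_sequence: str
    divergence: float


@dataclass
class TruthSet:
    ancestor_protein: str
    ancestor_cds: str
    regions: dict[str, tuple[int, int]]  # 1-based inclusive spans on the protein
    paralogs: list[ParalogTruth]


def _rand_protein(rng, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _back_translate(rng, protein: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    )


def build_ancestor(rng) -> tuple[str, dict[str, tuple[int, int]]]:
    """An ancestral precursor satisfying all architecture rules.

    Layout: ER signal (20, starts Met) / spacer (8) / PDP (Gly ... Asp with
    two Cys, ~14 residues) / GLDN tail / SSU (35, exactly 2 Cys) / spacer (8)
    / LSU (55, exactly 6 Cys).  Cys appears nowhere else; the PDP interior
    avoids Gly/Asp so the buried-peptide span is unambiguous.
    """
    no_cys = "ADEFGHIKLMNPQRSTVWY"
    no_cys_gly = "ADEFHIKLMNPQRSTVWY"
    pdp_interior_alpha = "AEFHIKLMNPQRSTVWY"  # no C/D/G

    signal = "M" + _rand_protein(rng, 19, "AILVFSTWLL")
    spacer1 = _rand_protein(rng, 8, no_cys_gly)
    pdp_len = int(rng.integers(12, 17))
    interior = list(_rand_protein(rng, pdp_len - 2, pdp_interior_alpha))
    cys_pos = rng.choice(np.arange(len(interior)), size=2, replace=False)
    for p in cys_pos:
        interior[p] = "C"
    pdp = "G" + "".join(interior) + "D"
    tail = "GLDN"
    ssu = list(_rand_protein(rng, 35, no_cys))
    for p in (4, 19):
        ssu[p] = "C"
    ssu = "".join(ssu)
    spacer2 = _rand_protein(rng, 8, no_cys)
    lsu = list(_rand_protein(rng, 55, no_cys))
    for p in (3, 15, 19, 30, 34, 47):
        lsu[p] = "C"
    lsu = "".join(lsu)

    protein = signal + spacer1 + pdp + tail + ssu + spacer2 + lsu
    spans = {}
    pos = 1
    for name, part in (
        ("er_signal", signal), ("spacer1", spacer1), ("pdp", pdp),
        ("tail", tail), ("ssu", ssu), ("spacer2", spacer2), ("lsu", lsu),
    ):
        spans[name] = (pos, pos + len(part) - 1)
        pos += len(part)
    return protein, spans


def _mutate_cds(
    rng,
    cds: str,
    regions: Mapping[str, tuple[int, int]],
    rate: float,
    pdp_multiplier: float,
) -> str:
    """Substitution-only evolution with rule-preserving rejection sampling."""
    pdp_a, pdp_b = regions["pdp"]
    tail_a, tail_b = regions["tail"]
    ssu = regions["ssu"]
    lsu = regions["lsu"]
    seq = list(cds)
    n_codons = len(cds) // 3

    def aa_index(i_nt: int) -> int:
        return i_nt // 3

    protected_codons = {0, n_codons - 1}  # start Met and stop
    protected_codons.update({pdp_a - 1, pdp_b - 1})  # PDP boundary G / D
    protected_codons.update(range(tail_a - 1, tail_b))  # GLDN tail
    # conserved Cys codons
    for span in (regions["pdp"], ssu, lsu):
        for ai in range(span[0] - 1, span[1]):
            if _CODON_TO_AA["".join(cds[3 * ai : 3 * ai + 3])] == "C":
                protected_codons.add(ai)

    constrained = {}
    for ai in range(pdp_a - 1, pdp_b - 1 - 1 + 1):
        constrained[ai] = "pdp"
    for span, tag in ((ssu, "albumin"), (lsu, "albumin")):
        for ai in range(span[0] - 1, span[1]):
            constrained[ai] = tag

    site_rate = np.full(len(cds), rate)
    site_rate[3 * (pdp_a - 1) : 3 * pdp_b] = min(0.9, rate * pdp_multiplier)
    hits = np.nonzero(rng.random(len(cds)) < site_rate)[0]
    for i in hits:
        ai = aa_index(i)
        if ai in protected_codons:
            continue
        old = seq[i]
        new = _BASES[rng.integers(0, 4)]
        while new == old:
            new = _BASES[rng.integers(0, 4)]
        seq[i] = new
        codon = "".join(seq[3 * ai : 3 * ai + 3])
        aa = _CODON_TO_AA[codon]
        tag = constrained.get(ai)
        bad = (
            aa == "*"
            or (tag is not None and aa == "C")  # no gained conserved Cys
            or (tag == "pdp" and aa == "G")  # keep the PDP span unambiguous
        )
        if bad:
            seq[i] = old
    return "".join(seq)


def _translate_cds(cds: str) -> str:
    return "".join(_CODON_TO_AA["".join(cds[i : i + 3])] for i in range(0, len(cds) - 3, 3))


def generate_precursor_family(spec: FamilySpec) -> TruthSet:
    """Ancestor + seeded paralogs with per-paralog divergence and truth labels."""
    rng = np.random.default_rng(spec.seed)
    protein, regions = build_ancestor(rng)
    cds = _back_translate(rng, protein) + "TAA"

    paralogs: list[ParalogTruth] = []
    for i in range(spec.n_paralogs):
        div = float(spec.mean_divergence * rng.uniform(0.2, 1.8))
        p_cds = cds
        is_pawl = rng.random() < spec.pawl_fraction
        if is_pawl:
            p_cds = _strip_pdp_cys(rng, p_cds, regions)
        p_cds = _mutate_cds(rng, p_cds, regions, div, spec.pdp_rate_multiplier)
        p_protein = _translate_cds(p_cds)
        pdp_seq = p_protein[regions["pdp"][0] - 1 : regions["pdp"][1]]
        label = "PawL1" if pdp_seq.count("C") == 0 else "PawS1"
        paralogs.append(
            ParalogTruth(f"paralog_{i + 1:02d}", p_protein, p_cds, label, pdp_seq, div)
        )
    return TruthSet(protein, cds, regions, paralogs)


def _strip_pdp_cys(rng, cds: str, regions: Mapping[str, tuple[int, int]]) -> str:
    """Replace the PDP Cys codons with Ser: the PawL-type loss of the pair."""
    a, b = regions["pdp"]
    seq = list(cds)
    for ai in range(a - 1, b):
        codon = "".join(seq[3 * ai : 3 * ai + 3])
        if _CODON_TO_AA[codon] == "C":
            repl = ("AGT", "AGC", "TCA", "TCT")[rng.integers(0, 4)]
            seq[3 * ai : 3 * ai + 3] = list(repl)
    return "".join(seq)


# ---------------------------------------------------------------------------
# transcriptome + abundances


def generate_transcriptome(
    truth: Optional[TruthSet],
    scale: float = DEFAULT_SCALE,
    family_depth: Optional[float] = None,
    family_depth_spread: float = 0.0,
    include_core: bool = True,
    utr_length: int = 25,
    seed: int = 0,
):
    """Transcript sequences plus an abundance (target depth) table.

    Core-gene stand-ins are emitted at depths proportional to the observed
    tier anchors times ``scale``; the family sits at its own tier (default
    the family anchor x scale).  ``family_depth_spread`` > 0 draws per-paralog
    depths log-uniformly within 10**(+-spread) of the family depth, giving the
    heterogeneous abundances real families show.

    Returns (transcripts, abundances, core_genes): a list of (name, sequence),
    a dict name -> depth, and the CoreGene stand-in records (protein queries
    for the QC suite).
    """
    from .assembly_qc import CoreGene

    rng = np.random.default_rng(seed)
    transcripts: list[tuple[str, str]] = []
    abundances: dict[str, float] = {}
    core_genes: list[CoreGene] = []

    def add(name: str, cds: str, depth: float) -> None:
        utr5 = _rand_dna(rng, utr_length)
        utr3 = _rand_dna(rng, utr_length)
        transcripts.append((name, utr5 + cds + utr3))
        abundances[name] = depth

    if truth is not None:
        base = family_depth if family_depth is not None else FAMILY_TIER * scale
        for p in truth.paralogs:
            d = base
            if family_depth_spread > 0:
                d = base * 10 ** rng.uniform(-family_depth_spread, family_depth_spread / 3)
            add(p.name, p.cds, float(d))

    if include_core:
        for name, aa_len, anchor in CORE_TIERS:
            protein = "M" + _rand_protein(rng, aa_len - 1, "ACDEFGHIKLMNPQRSTVWY")
            cds = _back_translate(rng, protein) + "TAA"
            add(name, cds, anchor * scale)
            core_genes.append(CoreGene(name, protein, anchor * scale))
    return transcripts, abundances, core_genes


def _rand_dna(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    transcripts: Sequence[tuple[str, str]],
    abundances: Mapping[str, float],
    spec: ReadSimSpec = ReadSimSpec(),
) -> list[tuple[QualityRead, QualityRead]]:
    """Paired-end reads at per-transcript target depths.

    Fragments are drawn uniformly along the transcript with Normal insert
    sizes; mate 1 reads the fragment start on the forward strand, mate 2 the
    fragment end reverse-complemented.  Substitution errors are injected per
    base; quality strings decay linearly 5'->3' with Gaussian jitter, and
    erroneous bases are assigned lower scores on average.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length
    pairs: list[tuple[QualityRead, QualityRead]] = []
    for name, seq in transcripts:
        depth = abundances.get(name, 0.0)
        if depth <= 0:
            continue
        if len(seq) < L:
            continue  # too short to sequence at this read length
        n_pairs = max(1, int(round(depth * len(seq) / (2 * L))))
        for i in range(n_pairs):
            frag = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
            frag = max(L, min(frag, len(seq)))
            start = int(rng.integers(0, len(seq) - frag + 1))
            fragment = seq[start : start + frag]
            r1 = _make_read(rng, fragment[:L], f"{name}_{i}/1", "first", spec)
            r2 = _make_read(
                rng, reverse_complement(fragment[-L:]), f"{name}_{i}/2", "second", spec
            )
            pairs.append((r1, r2))
    return pairs


def _make_read(rng, template: str, rid: str, mate: str, spec: ReadSimSpec) -> QualityRead:
    n = len(template)
    ramp = np.arange(n) / max(n - 1, 1)
    q_end = spec.q_end
    if rng.random() < spec.bad_tail_fraction:
        q_end -= spec.bad_tail_drop
    qual = spec.q_start + (q_end - spec.q_start) * ramp
    qual = qual + rng.normal(0, spec.q_read_sd) + rng.normal(0, spec.q_jitter, n)
    errors = rng.random(n) < spec.error_rate
    seq = list(template)
    for i in np.nonzero(errors)[0]:
        alt = _BASES[rng.integers(0, 4)]
        while alt == seq[i]:
            alt = _BASES[rng.integers(0, 4)]
        seq[i] = alt
        qual[i] -= 12.0
    q = tuple(int(x) for x in np.clip(np.rint(qual), 2, 40))
    return QualityRead(rid, "".join(seq), q, mate)


# ---------------------------------------------------------------------------
# recovery assessment


@dataclass
class RecoveryReport:
    status: dict[str, str]  # paralog name -> recovered | partial | missed

    @property
    def recovered(self) -> set[str]:
        return {n for n, s in self.status.items() if s in ("recovered", "partial")}

    @property
    def n_exact(self) -> int:
        return sum(s == "recovered" for s in self.status.values())


def end_to_end_recovery(
    truth: TruthSet,
    annotations: Sequence[PrecursorAnnotation],
    partial_coverage: float = 0.30,
    min_identity: float = 98.0,
) -> RecoveryReport:
    """Per paralog: exact protein match, partial, or missed.

    'Partial' requires >= 30% of the truth protein aligned to some annotation
    at >= ``min_identity`` percent identity over the aligned span — the
    identity floor ties a fragment to that specific paralog rather than to a
    conserved region shared by the whole family.
    """
    proteins = [a.protein for a in annotations]
    status: dict[str, str] = {}
    for p in truth.paralogs:
        if any(p.protein == q for q in proteins):
            status[p.name] = "recovered"
            continue
        best_cov = 0.0
        for q in proteins:
            if not q:
                continue
            score, ident, q_span, _ = local_align_protein(p.protein, q)
            if score <= 0 or ident < min_identity:
                continue
            cov = (q_span[1] - q_span[0] + 1) / len(p.protein)
            best_cov = max(best_cov, cov)
        status[p.name] = "partial" if best_cov >= partial_coverage else "missed"
    return RecoveryReport(status)


def word_size_sweep_recovery(
    truth: TruthSet,
    reads: Iterable,
    k_list: Sequence[int],
    query_protein: Optional[str] = None,
    min_contig_length: int = 300,
    min_score: float = 40.0,
):
    """Assemble at each word size, mine each assembly, score recovery.

    Returns (per_k, union_recovered): per-k RecoveryReport plus the union of
    paralog names recovered (fully or partially) at any word size.
    """
    from .assembler import AssemblyParams, multi_k_assemble
    from .precursor_annotator import mine_transcriptome

    query = query_protein if query_protein is not None else truth.ancestor_protein
    params = AssemblyParams(min_contig_length=max(min_contig_length, max(k_list)))
    assemblies = multi_k_assemble(reads, k_list, params)
    per_k: dict[int, RecoveryReport] = {}
    union: set[str] = set()
    for k, asm in assemblies.items():
        anns = mine_transcriptome(
            asm.contigs, query, truth.ancestor_protein, truth.regions, min_score=min_score
        )
        rep = end_to_end_recovery(truth, anns)
        per_k[k] = rep
        union |= rep.recovered
    return per_k, union


# ---------------------------------------------------------------------------
# truth export


def write_truth(truth: TruthSet, fasta_path=None, tsv_path=None) -> None:
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            fh.write(f">ancestor\n{truth.ancestor_protein}\n")
            for p in truth.paralogs:
                fh.write(f">{p.name} {p.class_label}\n{p.protein}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("name\tclass\tdivergence\tpdp\n")
            for p in truth.paralogs:
                fh.write(f"{p.name}\t{p.class_label}\t{p.divergence:.4f}\t{p.pdp_sequence}\n")
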