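# Methods

This note documents the models, parameter choices and numerical conventions
behind `seedfam`, and what the synthetic-data tests do and do not establish
about real data.

## Read quality control

Trimming follows the FASTX `fastq_quality_trimmer` convention: bases are
removed from the 3' end while the terminal base quality is below `t`
(default 30); reads shorter than `l` (default 50) afterwards are discarded.
Filtering follows `fastq_quality_filter`: a read is kept iff at least `p`%
(default 90) of its bases have quality ≥ `q` (default 30), with the
comparison inclusive and N bases counted as failing regardless of their
score.  Quality encoding is Phred+33; a Phred score Q corresponds to an
error probability of 10^(−Q/10), so Q30 means 99.9% and Q20 means 99%
base-call accuracy.

Two pipeline modes mirror the two pre-assembly routes: `combined_single`
pools both mates, trims, filters and collapses exact duplicates
(`fastx_collapser` ordering: descending multiplicity, ties lexicographic);
`per_mate_paired` processes each mate and keeps a pair only when both
mates survive.  Orphan handling is drop-the-whole-pair, which keeps
downstream pairing trivial; when a pair is dropped, both reads are charged
to the stage that caused the drop so that
`raw = clean + trimmed_discarded + filter_discarded` holds exactly.

## Assembler

The graph is built over canonical k-mers (lexicographic minimum of a k-mer
and its reverse complement; a palindromic k-mer is its own canonical form)
with occurrence counts as coverage; k-mers containing N are skipped.
Adjacency is (k−1)-overlap in both orientations.  Contigs are maximal
non-branching paths after simplification, emitted in the lexicographically
smaller orientation, ordered by descending length then sequence, and named
`contig_<n>` — making output byte-deterministic for fixed input.

Simplification alternates two operations to a fixpoint:

* **tips** — a unitig that dead-ends on one side, attaches to a branch on
  the other, spans at most `tip_length_limit` nodes (default 2k) and has
  lower mean coverage than the best sibling branch at the junction is
  removed;
* **bubbles** — two unitigs sharing their single predecessor and single
  successor whose lengths differ by at most `bubble_size` bases
  (default 50) collapse onto the higher-coverage path (ties keep the
  lexicographically smaller sequence).

These heuristics are a functional analogue of a commercial assembler's
unpublished cleaning steps; no bit-exact equivalence is claimed.  The
word-size bounds are 11–64; minimum contig length defaults follow the two
assembly routes (100 for the automatic-word-size route, 300 for the
paired-sweep route).  No coverage-based contig filtering is applied beyond
length.

Scaffolding estimates the insert distribution (median/MAD) from pairs whose
mates both place uniquely on one contig, using exact-seed voting for
placement; contig pairs linked by ≥ `min_link_pairs` (default 3) spanning
pairs in a single consistent relative orientation are joined with an N-run
of the estimated gap (floor 1).  A competing orientation with equal support
blocks the join.

The multi-k sweep assembles at each distinct word size and merges the
contig pools, discarding a contig whose identity to a longer kept contig is
≥ 99% over the aligned span (strand-insensitive, computed with edlib).

## Translated search

Contigs are translated in all six frames (standard code, stops as `*`,
N-containing codons as X) and aligned locally to the protein query under
BLOSUM62 with affine gaps, existence 11 / extension 1 — conventional
tBLASTn-style scoring.  The matrix's `*` row/column is set to −10 so
optimal local alignments effectively cannot cross an in-frame stop:
precursor ORFs are contiguous.  There is no E-value model; the reporting
threshold is a raw score (default 40 substitution units) appropriate for
single-assembly screens with a ~150-residue query.  The core-transcript
suite screens with a threshold of 60 because its queries are 104–509
residues and the random-score regime of long queries against unrelated
contigs reaches beyond 40.  Alignment is delegated to Biopython's
`PairwiseAligner`; tests verify its scores against an independent
hand-written Gotoh dynamic program on small instances.

## Precursor annotation

Region boundaries are inferred by end-gap-free global alignment of the
candidate to a reference precursor of known architecture and projecting
each reference region through the alignment; an alignment identity below
20% (normalised by the shorter sequence, so fragments are not penalised)
aborts annotation.  The buried-peptide span is then refined locally: a
qualifying span starts Gly, ends Asp, is 10–40 residues long (observed
PDPs run 12–22; the bounds add margin and are configurable) and is
followed by a four-residue tail matching GLDN in at least 2 of 4 positions
("in most cases" the tail is exactly GLDN, hence the tolerance).  Among
qualifying spans the one whose end sits closest to the projected SSU start
wins (ties: shortest, then leftmost) — the planted/biological peptide abuts
the small subunit, so decoy Gly…Asp stretches elsewhere in the window lose.

Classification: `PawS1` requires a PDP with exactly 2 Cys plus an SSU with
exactly 2 and an LSU with exactly 6 Cys; `PawL1` is the same with a
Cys-free PDP; `albumin_only` passes the subunit checks without a
qualifying PDP.  Checks on absent regions are skipped and downgrade
confidence to `partial` instead of rejecting — partial transcripts carry
real information (the PDP plus tail is recognisable even in short
fragments).  Cys counts are enforced strictly only on complete regions.
LSU length is deliberately unconstrained (expanded LSUs occur).  ORF
calling keeps Met-less segments as 5'-truncated fragments; the upstream
in-frame stop frequently sits in UTR sequence carried by the contig.

## Assembly quality via core transcripts

Six control genes spanning the seed expression range anchor the suite,
with average-coverage tiers (LEA 174,360; OLE 9,894; AP 1,561; PR 503;
CP-1 126; PK 50) and the target family near 500.  Per gene the suite
reports the query-coverage % of the best translated hit (integer-rounded)
and the average coverage of the identified transcript — the sum of aligned
read bases divided by the reference length, counting reference-consuming
matched+mismatched bases only (whether soft-clipped bases should count is
unknowable for the original tool; this convention is documented and
self-consistent).  Mapping uses edit costs mismatch 2 / insertion 3 /
deletion 3 with inclusive acceptance thresholds of 80% aligned read
fraction and 80% identity over the aligned part, best placement only; a
fast unit-cost edlib scan locates candidates which are then rescored as
local alignments.  The verdict is positive iff both low-tier genes (CP-1,
PK) are at least partially recovered — presence of transcripts rarer than
the target family indicates the assembly reaches its abundance tier.

## Peptide mass prediction

Neutral monoisotopic mass = Σ standard residue masses + 18.010565 Da of
water for linear peptides (cyclisation condenses it out) − 2 × 1.0078250319
Da per disulfide.  Ion m/z = (M + z × 1.007276)/z; the default ion is the
doubly charged [M+2H]2+, the species observed for these peptides in seed
extracts.  Residue masses come from pyteomics' standard table.  PDPs with
two Cys are predicted as cyclic with one disulfide; Cys-free (PawL-type)
buried regions yield no stable peptide and are excluded by default; an odd
Cys count is emitted with zero disulfides and a warning flag.  Matching
against an observed mass list takes the nearest observed m/z per predicted
ion with a default tolerance of 0.05 Da — published predicted-vs-observed
deltas reach 0.03 Da, and reproducing published two-decimal predictions
with exact constants leaves residuals ≤ 0.015 Da, both absorbed by the
tolerance.  Reported m/z are rounded to two decimals.  The one validated
linear peptide (C-terminal Tyr instead of Asp, no cyclisation) is handled
by its `cyclic=False` flag; its printed mass is only consistent with the
acyclic formula.

## Simulator

The generator builds an ancestral precursor that satisfies every
architecture rule (signal 20 aa starting Met, spacer 8, PDP 12–16 aa with
two Cys, GLDN tail, SSU 35 aa with 2 Cys, spacer 8, LSU 55 aa with 6 Cys;
Cys nowhere else; PDP interior free of Gly/Asp so the span is unambiguous),
back-translates it with random synonymous codons, and derives paralogs by
substitution-only evolution: per-paralog divergence is drawn uniformly in
[0.2, 1.8] × `mean_divergence` (default 0.08 substitutions/site) and the
PDP block mutates at `pdp_rate_multiplier` (default 4) times the flanking
rate, reflecting the faster evolution of the buried peptide.  Mutations
that would break a rule the truth labels rely on — stop codons, gained or
lost conserved Cys, the boundary Gly/Asp, the tail — are rejected and the
site left unchanged, so labels stay decidable by construction.  A
`pawl_fraction` of paralogs has its PDP Cys pair substituted to Ser before
evolution (the PawL-type loss).  Indels are not modelled; observed
close paralogs differ almost entirely by substitutions, and the annotator's
span projection is exercised by truncation tests instead.

Transcriptomes attach 25-nt UTRs and assign depths: core genes at their
tier anchors times a desk scale (default 1/100, so the full suite runs in
minutes — at that scale the two lowest tiers are intentionally too shallow
to assemble, and tests that need them use constructed assemblies), the
family at ~50× with an optional log-uniform per-paralog spread
(10^[−spread, +spread/3]) emulating heterogeneous paralog expression.

Reads are 2×101 paired-end: Normal insert (mean 300, sd 30) clipped to the
transcript, mate 1 from the fragment start, mate 2 reverse-complemented
from the end; substitution errors at 0.2% per base.  Qualities decay
linearly from Q37 to Q35 with per-base jitter (sd 3) and a per-read
baseline shift (sd 1.5); 10% of reads have their 3' end decay a further 12
points, and erroneous bases score 12 lower.  This calibration was chosen so
that the canonical (q30, p90) filter removes a minority of reads (~25%)
while (q22, p90) removes almost none — the direction and regime observed on
real seed datasets; a steeper decay to Q25 would make the q30 filter
remove every simulated read, leaving no study conditions to emulate.

Recovery bookkeeping: a paralog is `recovered` on an exact protein match,
`partial` when ≥ 30% of its protein aligns to some annotation at ≥ 98%
identity over the aligned span.  The identity floor is essential: family
members are ~85% identical to each other, so without it any conserved
fragment would "recover" every paralog and per-word-size comparisons would
saturate.

## What the synthetic tests show — and do not

The word-size sweep experiment (15-paralog families, heterogeneous
divergence and depth, k ∈ {23, 45, 60, 62}) reproduces the qualitative
claim that the union over word sizes recovers at least as many paralogs as
the best single word size, strictly more in a substantial fraction of
seeds: large k separates similar paralogs, small k tolerates shallow
coverage.  Desk-scale problem sizes (hundreds to thousands of read pairs,
transcripts ~500 nt) keep the whole suite in minutes on one CPU; they do
not emulate 10^8-read datasets, real expression dispersion, splice
variants, indel evolution, machine-specific error models or PCR
duplicates, so passing tests demonstrate correctness of the algorithms
under the stated model, not performance claims on workstation-scale data.
At k = 62 the sweep's low-depth paralogs fragment because 101-nt reads
must overlap by 61 nt; that behaviour is the mechanism under study, not an
artefact.

Numerical conventions throughout: 1-based inclusive coordinates in all
reports; deterministic tie-breaks (score, then numeric-aware contig id;
descending length, then lexicographic sequence); all randomness flows from
explicit integer seeds and every generator is byte-reproducible under its
seed.
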