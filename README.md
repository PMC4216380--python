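# seedfam

Mining a rapidly evolving seed-protein gene family from RNA-seq by de novo
transcriptome assembly.

## The problem

Napin-type seed storage albumin precursors of the PawS1 family
(Preproalbumin with SFTI-1) mature into two products: a heterodimeric
albumin and, buried between the first spacer and the albumin small subunit,
a short disulfide-bonded cyclic peptide (a PawS-Derived Peptide, PDP).
These genes evolve quickly — the PDP block faster than the flanking albumin
— and many Asteraceae species carry several near-identical paralogs, so
PCR with conserved primers cannot enumerate them.  Seed RNA-seq can:
assemble the seed transcriptome de novo, screen it with a protein query,
and confirm predicted peptides by their monoisotopic masses in LC-MS.

The catch is that the assembler's **word size** (k-mer length) decides
whether near-identical paralogs merge into one tangled graph or separate
into distinct contigs, and no single word size recovers every family
member.  `seedfam` implements the full desk workflow and makes the word
size a first-class sweep parameter:

1. **read_qc** — FASTX-style trimming (3' bases below quality `t`, minimum
   length `l`), filtering (at least `p`% of bases at quality `q`, with
   Phred error probability 10^(−Q/10)), and duplicate collapsing.
2. **assembler** — a canonical-k-mer de Bruijn assembler with tip removal,
   bubble popping, length filtering, paired-end scaffolding and a multi-k
   sweep whose union merges contigs at ≥99% identity.
3. **translated_search** — a tBLASTn-like screen: six-frame translation and
   BLOSUM62 local alignment (gap open 11 / extend 1) of a protein query
   against every contig.
4. **precursor_annotator** — architecture rules: ER signal and spacers
   projected from a reference precursor, a buried peptide that starts Gly,
   ends Asp, carries 0 or 2 Cys and is followed by a GLDN-like tail, an SSU
   with 2 and an LSU with 6 conserved Cys; classes `PawS1`, `PawL1`,
   `albumin_only`, `none`.
5. **assembly_qc** — a core-transcript quality suite: per control gene the
   query-coverage % of the best hit and the average read coverage
   (Σ aligned bases / reference length) under mapping thresholds of 80%
   length fraction and 80% similarity.
6. **peptide_mass** — monoisotopic [M+zH]z+ prediction for PDPs
   (head-to-tail cyclisation −18.011 Da, each disulfide −2.016 Da) and
   matching against an observed LC-MS mass list.
7. **simulator** — seeded synthetic families, tiered transcriptomes and
   2×101 paired-end reads, so every stage is testable without downloads.

## Worked example

Simulate a five-paralog family (20% of paralogs PawL-type), assemble at
word size 60, annotate, and predict peptide masses:

```python
from seedfam import simulator, assembler, precursor_annotator, peptide_mass

spec = simulator.FamilySpec(n_paralogs=5, mean_divergence=0.08,
                            pawl_fraction=0.2, seed=7)
truth = simulator.generate_precursor_family(spec)
transcripts, depths, _ = simulator.generate_transcriptome(
    truth, family_depth=60, include_core=False, seed=7)
pairs = simulator.simulate_reads(transcripts, depths,
                                 simulator.ReadSimSpec(seed=7))
reads = [r.sequence for pair in pairs for r in pair]

assembly = assembler.assemble(
    reads, assembler.AssemblyParams(word_size=60, min_contig_length=300))
print(f"{len(pairs)} read pairs -> {assembly.stats.contig_count} contigs, "
      f"N50 {assembly.stats.n50}")

annotations = precursor_annotator.mine_transcriptome(
    assembly.contigs, truth.ancestor_protein, truth.ancestor_protein,
    truth.regions)
for ann in annotations:
    print(ann.orf.contig_id, ann.class_label, ann.pdp_sequence or "-")

table = peptide_mass.predict_pdp_ion_table(annotations)
print(table.to_string(index=False))
```

prints

```
720 read pairs -> 5 contigs, N50 485
contig_2 PawS1 GPNCPNCSIRRMTD
contig_4 PawS1 GNICTNCPTRKKVD
contig_5 PawS1 GNECPNCTTRKNYD
contig_1 PawL1 GNNAPNSTIRQKYD
contig_3 PawL1 GNNSIYSTLSQESD
      sequence  cyclic  n_disulfides  charge  predicted_mz warning
GNECPNCTTRKNYD    True             1       2        797.82
GNICTNCPTRKKVD    True             1       2        764.87
GPNCPNCSIRRMTD    True             1       2        772.33
```

All five planted paralogs separate at word size 60; the two PawL-type
precursors (Cys-free buried region, no stable peptide) are excluded from
the mass table by default.  Each `predicted_mz` is the doubly charged
[M+2H]2+ ion of the backbone-cyclic, disulfide-oxidised peptide.

The same workflow is available from the shell:

```sh
seedfam simulate --n-paralogs 15 --depth 50 --seed 1 -o sim/
seedfam qc sim/reads_R1.fastq sim/reads_R2.fastq --t 30 --l 50 --q 30 --p 90 -o qc/
seedfam sweep qc/clean_R1.fastq qc/clean_R2.fastq --k 23,45,60,62 -o asm/
seedfam annotate asm/contigs_union.fasta sim/reference.fasta \
    sim/reference.fasta sim/reference_regions.yaml -o annotations.tsv
seedfam mass annotations.tsv -o masses.tsv
```

or as one reproducible run (`seedfam run --config run.yaml`), which writes
per-stage reports and a manifest with content hashes.

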