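"""ORF calling, region projection, PDP detection and precursor classification."""

import pytest

from seedfam import simulator
from seedfam.assembler import AssemblyParams, assemble, reverse_complement
from seedfam.precursor_annotator import (
    REGION_ORDER,
    classify_precursor,
    delimit_regions,
    detect_pdp,
    find_orfs,
    merge_overlapping_orfs,
    mine_transcriptome,
)
from tests.conftest import random_dna


def _cds_for(protein: str) -> str:
    import numpy as np

    return simulator._back_translate(np.random.default_rng(0), protein)


class TestFindOrfs:
    def test_complete_orf(self, small_family):
        protein = small_family.ancestor_protein
        contig = "ATT" + _cds_for(protein) + "TAAGGG"
        orfs = find_orfs(contig, frame_hint=1, min_protein_length=60)
        assert len(orfs) == 1
        assert orfs[0].protein == protein
        assert orfs[0].completeness == "complete"

    def test_truncated_orf_missing_stop(self, small_family):
        protein = small_family.ancestor_protein
        contig = _cds_for(protein)[:-30]  # no stop codon in frame
        orfs = find_orfs(contig, frame_hint=1, min_protein_length=60)
        assert orfs and orfs[0].completeness == "missing_stop"

    def test_min_length_filter(self):
        contig = "ATG" + _cds_for("A" * 40) + "TAA"
        assert find_orfs(contig, min_protein_length=80) == []

    def test_reverse_frame_span_consistent(self, small_family):
        protein = small_family.ancestor_protein
        fwd = "AT" + _cds_for(protein) + "TAACC"
        rev = reverse_complement(fwd)
        orfs = find_orfs(rev, min_protein_length=60)
        hit = [o for o in orfs if o.protein == protein]
        assert hit and hit[0].frame < 0


class TestDelimit:
    def test_reference_against_itself(self, small_family):
        truth = small_family
        ann = delimit_regions(truth.ancestor_protein, truth.ancestor_protein, truth.regions)
        assert {k: ann.regions[k] for k in truth.regions} == dict(truth.regions)

    def test_substitutions_outside_boundaries_keep_spans(self, small_family):
        truth = small_family
        p = list(truth.ancestor_protein)
        # mutate three residues inside spacer1/ssu/lsu interiors, away from edges
        for region, offset in (("spacer1", 3), ("ssu", 10), ("lsu", 25)):
            i = truth.regions[region][0] - 1 + offset
            p[i] = "W" if p[i] != "W" else "F"
        ann = delimit_regions("".join(p), truth.ancestor_protein, truth.regions)
        assert {k: ann.regions[k] for k in truth.regions} == dict(truth.regions)

    def test_truncated_protein_lacks_signal_but_keeps_rest(self, small_family):
        truth = small_family
        cut = truth.regions["spacer1"][1]  # start right at the PDP
        frag = truth.ancestor_protein[cut:]
        ann = delimit_regions(frag, truth.ancestor_protein, truth.regions)
        assert "er_signal" not in ann.regions
        assert "pdp" in ann.regions and "lsu" in ann.regions
        a, b = ann.regions["pdp"]
        assert frag[a - 1] == "G" and frag[b - 1] == "D"

    def test_unrelated_protein_yields_none(self, small_family):
        ann = delimit_regions("W" * 140, small_family.ancestor_protein, small_family.regions)
        assert ann.class_label == "none" and not ann.regions


class TestDetectPdp:
    def test_known_pdp_with_tail(self):
        protein = "SSAAVV" + "GPCYSYQSCFPD" + "GLDN" + "SSEEFF"
        found = detect_pdp(protein, (1, len(protein)), projected_ssu_start=23)
        assert found is not None
        (a, b), (ta, tb), _ = found
        assert protein[a - 1 : b] == "GPCYSYQSCFPD"
        assert protein[ta - 1 : tb] == "GLDN"

    def test_cys_free_span_is_admissible(self):
        protein = "SSAAVV" + "GAAYSYQSAFPD" + "GLDN" + "SSEEFF"
        found = detect_pdp(protein, (1, len(protein)), projected_ssu_start=23)
        (a, b), _, _ = found
        assert protein[a - 1 : b].count("C") == 0

    def test_no_admissible_span(self):
        assert detect_pdp("SSAAVVKKEEFFLLMMNN", (1, 18)) is None

    def test_tail_similarity_threshold(self):
        # tail 'PFWW' shares 0/4 with GLDN: the span must be rejected
        protein = "GPCYSYQSCFPD" + "PFWW" + "SS"
        assert detect_pdp(protein, (1, len(protein))) is None


def _build_annotation(pdp: str, ssu_cys=2, lsu_cys=6):
    signal = "M" + "A" * 19
    spacer1 = "SSSSSSSS"
    tail = "GLDN"
    ssu = ("C" * ssu_cys + "A" * (20 - ssu_cys))
    spacer2 = "TTTTTT"
    lsu = ("C" * lsu_cys + "E" * (40 - lsu_cys))
    protein = signal + spacer1 + pdp + tail + ssu + spacer2 + lsu
    regions, pos = {}, 1
    for name, part in (
        ("er_signal", signal), ("spacer1", spacer1), ("pdp", pdp), ("tail", tail),
        ("ssu", ssu), ("spacer2", spacer2), ("lsu", lsu),
    ):
        regions[name] = (pos, pos + len(part) - 1)
        pos += len(part)
    return delimit_regions(protein, protein, regions)


class TestClassify:
    def test_two_cys_pdp_is_paws(self):
        ann = _build_annotation("GPCYSYQSCFPD")
        assert classify_precursor(ann) == "PawS1"
        assert ann.pdp_cys_count == 2

    def test_cys_free_pdp_is_pawl(self):
        ann = _build_annotation("GAAYSYQSAFPD")
        assert classify_precursor(ann) == "PawL1"

    def test_no_pdp_is_albumin_only(self, small_family):
        truth = small_family
        # excise the PDP+tail block entirely
        p = truth.ancestor_protein
        a, b = truth.regions["pdp"][0] - 1, truth.regions["tail"][1]
        chopped = p[:a] + p[b:]
        ann = delimit_regions(chopped, truth.ancestor_protein, truth.regions)
        assert classify_precursor(ann) == "albumin_only"

    def test_wrong_ssu_cys_count_blocks_class(self):
        ann = _build_annotation("GPCYSYQSCFPD", ssu_cys=3)
        assert classify_precursor(ann) in ("albumin_only", "none")
        assert classify_precursor(ann) != "PawS1"

    def test_region_order_invariant(self, small_family):
        truth = small_family
        for p in truth.paralogs:
            ann = delimit_regions(p.protein, truth.ancestor_protein, truth.regions)
            classify_precursor(ann)
            present = [r for r in REGION_ORDER if r in ann.regions]
            spans = [ann.regions[r] for r in present]
            assert all(a2 > b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))


class TestAccuracyOnRuleConformingFamilies:
    def test_twenty_seeded_families_classified_perfectly(self):
        """Divergence <= 30%, complete regions: labels are decidable, so the
        annotator must match truth exactly (including PawL paralogs)."""
        n_total = 0
        for seed in range(20):
            truth = simulator.generate_precursor_family(
                simulator.FamilySpec(
                    n_paralogs=6, mean_divergence=0.10, pawl_fraction=0.25, seed=seed
                )
            )
            for p in truth.paralogs:
                ann = delimit_regions(p.protein, truth.ancestor_protein, truth.regions)
                assert classify_precursor(ann) == p.class_label, (seed, p.name)
                assert ann.pdp_sequence == p.pdp_sequence
                n_total += 1
        assert n_total == 120


class TestMine:
    def test_planted_family_recovered_with_pdp_truth(self, small_family):
        truth = small_family
        txs, ab, _ = simulator.generate_transcriptome(
            truth, family_depth=80, include_core=False, seed=11
        )
        pairs = simulator.simulate_reads(txs, ab, simulator.ReadSimSpec(seed=11, error_rate=0.0))
        reads = [r.sequence for p in pairs for r in p]
        asm = assemble(reads, AssemblyParams(word_size=60, min_contig_length=300))
        anns = mine_transcriptome(
            asm.contigs, truth.ancestor_protein, truth.ancestor_protein, truth.regions
        )
        planted = {p.pdp_sequence for p in truth.paralogs}
        found = {a.pdp_sequence for a in anns if a.class_label == "PawS1"}
        assert found & planted  # planted peptides are recovered verbatim
        assert all(a.pdp_sequence in planted for a in anns if a.class_label == "PawS1")

    def test_empty_assembly_gives_empty(self, small_family):
        truth = small_family
        assert (
            mine_transcriptome([], truth.ancestor_protein, truth.ancestor_protein, truth.regions)
            == []
        )

    def test_pawl_among_paws_labelled_once(self, rng):
        truth = simulator.generate_precursor_family(
            simulator.FamilySpec(n_paralogs=4, mean_divergence=0.08, pawl_fraction=0.0, seed=42)
        )
        # convert one paralog to PawL-type at the CDS level
        pawl_cds = simulator._strip_pdp_cys(
            __import__("numpy").random.default_rng(1), truth.paralogs[0].cds, truth.regions
        )
        from seedfam.assembler import Contig

        contigs = [Contig("contig_1", pawl_cds, 1.0)] + [
            Contig(f"contig_{i + 2}", p.cds, 1.0) for i, p in enumerate(truth.paralogs[1:])
        ]
        anns = mine_transcriptome(
            contigs, truth.ancestor_protein, truth.ancestor_protein, truth.regions
        )
        labels = [a.class_label for a in anns]
        assert labels.count("PawL1") == 1
        assert labels.count("PawS1") == len(truth.paralogs) - 1

    def test_classification_invariant_under_synonymous_recoding(self, small_family):
        truth = small_family
        p = truth.paralogs[0]
        from seedfam.assembler import Contig
        import numpy as np

        recoded = simulator._back_translate(np.random.default_rng(99), p.protein) + "TAA"
        anns = mine_transcriptome(
            [Contig("c1", p.cds, 1.0)], truth.ancestor_protein, truth.ancestor_protein, truth.regions
        )
        anns2 = mine_transcriptome(
            [Contig("c1", recoded, 1.0)], truth.ancestor_protein, truth.ancestor_protein, truth.regions
        )
        assert anns and anns2
        assert anns[0].class_label == anns2[0].class_label
        assert anns[0].pdp_sequence == anns2[0].pdp_sequence


def test_merge_overlapping_orfs():
    a, b = "MKWVFLACLFTF", "CLFTFAGQSEPR"
    assert merge_overlapping_orfs(a, b, min_overlap=5) == "MKWVFLACLFTFAGQSEPR"
    assert merge_overlapping_orfs(a, b, min_overlap=6) is None
    assert merge_overlapping_orfs("MKWVFLAC", "WWWWYYYY", min_overlap=2) is None
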