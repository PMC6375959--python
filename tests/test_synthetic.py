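"""Community sampling, rearing shift, marker evolution, read generation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from algscreen.pcr import IUPAC_SETS, match_primer, packaged_primers
from algscreen.synthetic import (
    A3_MOTIF_NT,
    CommunitySpec,
    apply_rearing_shift,
    evolve_marker_genes,
    generate_reads,
    jitter_community,
    make_reference_proteins,
    sample_community,
    simulate_study,
)


class TestSampleCommunity:
    def test_single_taxon_is_unity(self):
        assert sample_community(CommunitySpec(1, seed=5)) == {"T001": 1.0}

    def test_fixed_seed_is_deterministic(self):
        spec = CommunitySpec(30, seed=11)
        assert sample_community(spec) == sample_community(spec)

    def test_normalized_and_rank_abundance_shape(self):
        comm = sample_community(CommunitySpec(50, sigma=1.5, seed=7))
        values = np.array(sorted(comm.values(), reverse=True))
        assert abs(values.sum() - 1.0) < 1e-12
        assert (np.diff(values) <= 0).all()
        assert (values > 0).all()

    def test_zero_taxa_is_error(self):
        with pytest.raises(ValueError):
            CommunitySpec(0)


class TestRearingShift:
    def test_identity_factors_preserve_community(self):
        spec = CommunitySpec(
            10, enriched_taxa=frozenset({"T001"}), depletion_factor=1.0,
            enrichment_factor=1.0, extinction_floor=0.0, seed=1,
        )
        comm = sample_community(spec)
        shifted = apply_rearing_shift(comm, spec)
        assert shifted == pytest.approx(comm)

    def test_two_taxon_hand_calculation(self):
        spec = CommunitySpec(
            2, enriched_taxa=frozenset({"T001"}), depletion_factor=1.0,
            enrichment_factor=3.0, extinction_floor=0.0,
        )
        shifted = apply_rearing_shift({"T001": 0.5, "T002": 0.5}, spec)
        assert shifted == pytest.approx({"T001": 0.75, "T002": 0.25})

    def test_richness_strictly_decreases_under_depletion(self):
        spec = CommunitySpec(
            50, enriched_taxa=frozenset({"T001", "T002"}), depletion_factor=0.1,
            enrichment_factor=5.0, extinction_floor=1e-4, seed=3,
        )
        comm = sample_community(spec)
        shifted = apply_rearing_shift(comm, spec)
        assert len(shifted) < len(comm)
        assert abs(sum(shifted.values()) - 1.0) < 1e-12

    def test_empty_community_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            apply_rearing_shift({}, CommunitySpec(1))

    def test_jitter_preserves_support_and_normalization(self):
        comm = sample_community(CommunitySpec(20, seed=2))
        noisy = jitter_community(comm, 0.5, seed=9)
        assert set(noisy) == set(comm)
        assert abs(sum(noisy.values()) - 1.0) < 1e-12


class TestEvolveMarkerGenes:
    def test_rate_zero_markers_identical(self):
        genomes = evolve_marker_genes(4, seed=0, rate=0.0)
        assert len({g.marker_16s for g in genomes}) == 1

    def test_low_rate_high_identity_and_determinism(self):
        a = evolve_marker_genes(2, seed=13, rate=0.05)
        b = evolve_marker_genes(2, seed=13, rate=0.05)
        assert [g.marker_16s for g in a] == [g.marker_16s for g in b]
        m1, m2 = (g.marker_16s for g in a)
        identity = sum(x == y for x, y in zip(m1, m2)) / len(m1)
        assert identity >= 0.85

    def test_motif_rate_zero_keeps_exact_primer_sites(self, primers):
        genomes = evolve_marker_genes(
            6, seed=4, rate=0.2, motif_rate=0.0, alg_taxa=frozenset({"T001", "T004"})
        )
        for g in genomes:
            for gene in g.alg_genes:
                fwd = match_primer(primers["ALG-f1"], gene)
                rev = match_primer(primers["ALG-r"], gene)
                assert fwd and rev
                assert all(s.mismatches == 0 for s in fwd + rev)

    def test_alg_taxa_always_carry_genes(self):
        genomes = evolve_marker_genes(
            10, seed=6, p_alg=0.0, alg_taxa=frozenset({"T003"})
        )
        carriers = {g.taxon_id for g in genomes if g.alg_genes}
        assert carriers == {"T003"}

    def test_amplicon_frame_is_stop_free(self, primers):
        from algscreen.filtering import six_frame_translate, stop_codon_filter
        from algscreen.pcr import amplify

        genomes = evolve_marker_genes(
            8, seed=8, rate=0.1, alg_taxa=frozenset(f"T{i + 1:03d}" for i in range(8))
        )
        for g in genomes:
            (gene,) = g.alg_genes
            (amp,) = amplify(gene, [primers["ALG-f1"], primers["ALG-f2"]], primers["ALG-r"])
            assert stop_codon_filter(six_frame_translate(amp.sequence))

    def test_bad_rate_is_error(self):
        with pytest.raises(ValueError):
            evolve_marker_genes(2, rate=0.9)


class TestGenerateReads:
    def test_error_free_single_taxon_reads_identical(self):
        genomes = evolve_marker_genes(1, seed=0, rate=0.0)
        samples = generate_reads(
            {"s1": {"T001": 1.0}}, genomes, depth=10, error_rate=0.0, seed=1
        )
        assert {r.sequence for r in samples[0].records} == {genomes[0].marker_16s}

    def test_depth_is_exact(self):
        genomes = evolve_marker_genes(3, seed=0)
        comm = {"T001": 0.5, "T002": 0.3, "T003": 0.2}
        samples = generate_reads({"s1": comm}, genomes, depth=4000, seed=2)
        assert samples[0].depth == 4000
        assert all(r.sample_id == "s1" for r in samples[0].records)

    def test_zero_depth_is_error(self):
        genomes = evolve_marker_genes(1, seed=0)
        with pytest.raises(ValueError, match="depth"):
            generate_reads({"s1": {"T001": 1.0}}, genomes, depth=0)

    def test_fixed_seed_reads_bit_identical(self):
        genomes = evolve_marker_genes(5, seed=3)
        comm = sample_community(CommunitySpec(5, seed=3))
        a = generate_reads({"s1": comm}, genomes, depth=100, seed=9)
        b = generate_reads({"s1": comm}, genomes, depth=100, seed=9)
        assert [r.sequence for r in a[0].records] == [r.sequence for r in b[0].records]

    def test_multinomial_counts_fit_abundances(self):
        """Chi-square goodness of fit of read counts vs abundances is not
        rejected at alpha=0.01 in at least 18 of 20 seeds."""
        genomes = evolve_marker_genes(5, seed=1, rate=0.3)
        comm = {f"T{i + 1:03d}": p for i, p in enumerate([0.4, 0.3, 0.15, 0.1, 0.05])}
        marker_of = {g.marker_16s: g.taxon_id for g in genomes}
        passed = 0
        for seed in range(20):
            samples = generate_reads({"s1": comm}, genomes, 10000, error_rate=0.0, seed=seed)
            counts = {t: 0 for t in comm}
            for r in samples[0].records:
                counts[marker_of[r.sequence]] += 1
            observed = np.array([counts[t] for t in sorted(comm)])
            expected = np.array([comm[t] * 10000 for t in sorted(comm)])
            if chisquare(observed, expected).pvalue > 0.01:
                passed += 1
        assert passed >= 18


class TestReferenceProteins:
    def test_family_is_deterministic_and_scaffolded(self):
        a = make_reference_proteins(8, seed=1)
        b = make_reference_proteins(8, seed=1)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        for r in a:
            assert r.sequence.startswith("YARSELRE")
            assert r.sequence.endswith("YFKAGSY")

    def test_packaged_file_matches_generator(self, reference_proteins):
        regenerated = make_reference_proteins(n=16, seed=20190214)
        assert [r.sequence for r in regenerated] == [
            r.sequence for r in reference_proteins
        ]


class TestSimulateStudy:
    def test_structure_and_determinism(self):
        a = simulate_study(n_taxa=12, n_wild=2, n_reared=2, depth=50, seed=21)
        b = simulate_study(n_taxa=12, n_wild=2, n_reared=2, depth=50, seed=21)
        assert len(a.samples) == 4
        assert {s.group_label for s in a.samples} == {"SH-W", "SH-R"}
        assert all(s.depth == 50 for s in a.samples)
        assert a.enriched_taxa == b.enriched_taxa
        for sa, sb in zip(a.samples, b.samples):
            assert [r.sequence for r in sa.records] == [r.sequence for r in sb.records]

    def test_reared_template_is_depleted_version_of_wild(self):
        study = simulate_study(n_taxa=40, n_wild=2, n_reared=2, depth=50, seed=2)
        assert set(study.reared_template) <= set(study.wild_template)
        assert len(study.reared_template) < len(study.wild_template)
        assert study.enriched_taxa <= set(study.reared_template)
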