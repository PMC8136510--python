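"""Ground-truthed generators: determinism, construction rules, round trips."""

import numpy as np
import pandas as pd
import pytest

from poease.counts import GeneAnnotation, annotate_snp_features
from poease.panel import read_panel_tsv, read_fasta
from poease.simulate import (
    CATEGORY_INTERVALS,
    LINE_OF_ORIGIN,
    PARENT_OF_ORIGIN,
    SimConfig,
    simulate_cross,
    simulate_reciprocal,
    simulate_sex_expression,
    simulate_toy_genome,
)


class TestSimulateCross:
    def test_same_seed_reproduces_identical_output(self, tmp_path):
        config = SimConfig(n_genes=30, seed=5)
        a, b = simulate_cross(config, 1), simulate_cross(config, 1)
        assert a.truth == b.truth
        for rep in a.raw_tables:
            pd.testing.assert_frame_equal(a.raw_tables[rep], b.raw_tables[rep])
        pd.testing.assert_frame_equal(a.tpm, b.tpm)

    def test_truth_shared_between_directions(self):
        d1, d2 = simulate_reciprocal(SimConfig(n_genes=30, seed=5))
        assert d1.truth == d2.truth
        assert {s.position for s in d1.panel} == {s.position for s in d2.panel}

    def test_true_category_consistent_with_classifier_thresholds(self):
        d1 = simulate_cross(SimConfig(n_genes=200, seed=3), 1)
        for t in d1.truth:
            low, high = CATEGORY_INTERVALS[t.true_category]
            assert low <= t.theta <= high

    def test_binomial_sampling_unbiased_at_half(self):
        # rho=0, theta=0.5, 1e5 SNP draws at depth 100: pooled maternal
        # fraction within 0.005 of 0.5
        from poease.simulate import _beta_binomial

        rng = np.random.default_rng(6)
        depth = np.full(100_000, 100)
        maternal = _beta_binomial(rng, depth, 0.5, rho=0.0)
        assert abs(maternal.sum() / depth.sum() - 0.5) < 0.005

    def test_overdispersed_sampling_keeps_the_mean(self):
        from poease.simulate import _beta_binomial

        rng = np.random.default_rng(6)
        depth = np.full(100_000, 100)
        maternal = _beta_binomial(rng, depth, 0.8, rho=0.05)
        assert abs(maternal.sum() / depth.sum() - 0.8) < 0.005
        # between-SNP variance well above the binomial expectation
        frac = maternal / 100
        assert frac.var() > 2 * 0.8 * 0.2 / 100

    def test_line_effect_gene_flips_between_directions(self):
        config = SimConfig(
            n_genes=40, category_proportions={"MB": 1.0},
            line_effect_fraction=1.0, overdispersion_rho=0.0, seed=8,
        )
        d1, d2 = simulate_reciprocal(config)

        def pooled_pm(direction, gene_id):
            m = t = 0
            for counts in direction.snp_counts.values():
                for c in counts:
                    if c.contig.replace("ctg", "g", 1) == gene_id:
                        m += c.maternal_count
                        t += c.maternal_count + c.paternal_count
            return m / t

        for truth in d1.truth[:10]:
            pm1 = pooled_pm(d1, truth.gene_id)
            pm2 = pooled_pm(d2, truth.gene_id)
            assert pm1 == pytest.approx(truth.theta, abs=0.05)
            assert pm2 == pytest.approx(1 - truth.theta, abs=0.05)

    def test_emitted_files_round_trip(self, tmp_path, small_reciprocal):
        config, (d1, _) = small_reciprocal
        d1.write(tmp_path)
        panel = read_panel_tsv(tmp_path / "panel.tsv")
        assert {(s.contig, s.position) for s in panel} == \
            {(s.contig, s.position) for s in d1.panel}
        from poease.counts import read_allele_counts

        rep = d1.design.replicate_ids[0]
        back = read_allele_counts(
            tmp_path / f"{rep}.tsv", panel,
            maternal_is_reference=d1.maternal_is_reference, replicate_id=rep,
        )
        assert sorted(back, key=lambda c: (c.contig, c.position)) == \
            sorted(d1.snp_counts[rep], key=lambda c: (c.contig, c.position))
        tpm = pd.read_csv(tmp_path / "tpm.tsv", sep="\t", index_col=0)
        assert np.allclose(tpm.values, d1.tpm.values)
        annotation = GeneAnnotation.from_gff(tmp_path / "genes.gff3")
        features = annotate_snp_features(back, annotation)
        for c in back:
            expected = d1.features[c.key]
            assert features[c.key].feature_class == "exonic"
            assert features[c.key].gene_ids == expected.gene_ids

    def test_invalid_proportions_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(category_proportions={"M": 0.5, "B": 0.4})


class TestToyGenome:
    def test_truth_row_count_equals_n_variants(self, toy_genome):
        assert len(toy_genome.truth) == 25

    def test_files_mutually_consistent(self, tmp_path, toy_genome):
        toy_genome.write(tmp_path)
        genome = read_fasta(tmp_path / "genome.fasta")
        assert genome == toy_genome.genome
        # VCF refs match the FASTA at their positions
        for row in toy_genome.truth.itertuples(index=False):
            assert genome[row.contig][row.position - 1] == row.ref

    def test_vcf_parses_into_discriminant_panel(self, tmp_path, toy_genome):
        from poease.panel import select_discriminant_snps, variant_sites_from_vcf

        toy_genome.write(tmp_path)
        sites = variant_sites_from_vcf(
            tmp_path / "variants.vcf", "line_a", "line_b")
        panel = select_discriminant_snps(sites)
        assert {(s.contig, s.position, s.maternal_allele, s.paternal_allele)
                for s in panel} == \
            {(s.contig, s.position, s.maternal_allele, s.paternal_allele)
             for s in toy_genome.panel}

    def test_determinism(self):
        a = simulate_toy_genome(n_genes=4, codons_per_gene=20, n_variants=8, seed=3)
        b = simulate_toy_genome(n_genes=4, codons_per_gene=20, n_variants=8, seed=3)
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestSexExpression:
    def test_pure_male_component_gives_spm_zero(self):
        from poease.metrics import spm_table

        male, female, _ = simulate_sex_expression(50, (1.0, 0.0, 0.0), seed=4)
        spm = spm_table(male, female)
        assert all(v == 0.0 for v in spm.values())

    def test_shared_component_is_symmetric(self):
        from poease.metrics import spm_table

        male, female, _ = simulate_sex_expression(4000, (0.0, 0.0, 1.0), seed=4)
        spm = spm_table(male, female)
        assert np.mean(list(spm.values())) == pytest.approx(0.5, abs=0.02)

    def test_same_seed_identical_tables(self):
        a = simulate_sex_expression(100, seed=9)
        b = simulate_sex_expression(100, seed=9)
        assert a == b
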