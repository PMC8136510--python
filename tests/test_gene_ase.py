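"""Gene-level ASE: pooling, exact binomial test, categories, G-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from poease.counts import FeatureAssignment, SnpAlleleCount
from poease.gene_ase import (
    GeneAseRecord,
    assign_scaffolds_to_chromosomes,
    classify_ase,
    exact_binomial_test,
    g_test_independence,
    gene_inclusion_filter,
    pool_gene_counts,
    replicate_homogeneity,
    validate_gene,
)


def enumeration_binomial_p(m, n):
    """Independent oracle: sum the Binomial(n, 1/2) mass over all outcomes
    no more likely than the observed one."""
    pmf = [math.comb(n, k) / 2**n for k in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[m] + 1e-12))


class TestExactBinomial:
    @pytest.mark.parametrize("m, n, expected", [
        (5, 10, 1.0),
        (10, 10, 0.001953125),   # 2 * (1/1024)
        (8, 10, 0.109375),       # 2 * (56/1024)
    ])
    def test_frozen_examples(self, m, n, expected):
        assert exact_binomial_test(m, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_for_all_n_up_to_25(self):
        for n in range(1, 26):
            for m in range(n + 1):
                assert exact_binomial_test(m, n) == pytest.approx(
                    enumeration_binomial_p(m, n), abs=1e-10
                ), (m, n)

    def test_zero_total_is_hard_error(self):
        with pytest.raises(ValueError):
            exact_binomial_test(0, 0)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=50, derandomize=True)
    def test_pvalue_in_unit_interval(self, n, data):
        m = data.draw(st.integers(0, n))
        assert 0.0 <= exact_binomial_test(m, n) <= 1.0


class TestClassifyAse:
    @pytest.mark.parametrize("p_m, rejected, category", [
        (0.50, False, "B"),
        (0.50, True, "B"),
        (0.97, True, "M"),
        (0.95, True, "M"),
        (0.80, True, "MB"),
        (0.65, True, "B"),      # closed B boundary wins
        (0.35, True, "B"),
        (0.20, True, "PB"),
        (0.05, True, "P"),
        (0.02, True, "P"),
        (0.97, False, "B"),     # un-rejected null forces B regardless of p_m
    ])
    def test_category_rules(self, p_m, rejected, category):
        assert classify_ase(p_m, rejected) == category

    def test_intervals_partition_unit_interval_when_rejected(self):
        grid = np.linspace(0, 1, 10001)
        cats = [classify_ase(p, True) for p in grid]
        assert set(cats) == {"M", "MB", "B", "PB", "P"}
        # every point maps to exactly one category (total function)
        assert len(cats) == len(grid)


class TestHomogeneityG:
    def test_identical_proportions_give_zero(self):
        g, df, p = replicate_homogeneity([(90, 10), (45, 5)])
        assert g == pytest.approx(0.0, abs=1e-12) and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_extreme_table(self):
        g, df, _ = replicate_homogeneity([(10, 0), (0, 10)])
        assert g == pytest.approx(40 * math.log(2), abs=1e-9)
        assert df == 1

    def test_duplicated_replicate_gives_zero_for_any_k(self):
        for k in (2, 3, 5):
            g, df, _ = replicate_homogeneity([(30, 10)] * k)
            assert g == pytest.approx(0.0, abs=1e-9) and df == k - 1

    def test_zero_total_replicate_excluded(self):
        g, df, _ = replicate_homogeneity([(10, 10), (0, 0), (10, 10)])
        assert df == 1


class TestGTestIndependence:
    def test_perfect_independence(self):
        g, df, p = g_test_independence([[10, 10], [10, 10]])
        assert g == pytest.approx(0.0, abs=1e-12) and df == 1

    def test_hand_computed_diagonal_table(self):
        g, df, _ = g_test_independence([[10, 0], [0, 10]])
        assert g == pytest.approx(40 * math.log(2), abs=1e-9) and df == 1

    def test_agrees_with_scipy_log_likelihood_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 200, size=(rng.integers(2, 5), rng.integers(2, 6)))
            g, df, p = g_test_independence(table)
            ref = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert g == pytest.approx(ref.statistic, rel=1e-12)
            assert df == ref.dof
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_to_row_and_column_permutation(self):
        table = np.array([[5, 9, 1], [12, 3, 7]])
        g0, *_ = g_test_independence(table)
        assert g_test_independence(table[::-1])[0] == pytest.approx(g0)
        assert g_test_independence(table[:, ::-1])[0] == pytest.approx(g0)

    def test_zero_column_dropped_with_df_adjustment(self):
        g, df, _ = g_test_independence([[10, 0, 5], [8, 0, 9]])
        assert df == 1


def make_counts(gene_snp_counts):
    """gene_snp_counts: {gene: {rep: [(m, p), ...]}} -> counts + features."""
    counts, features = [], {}
    for gi, (gene, reps) in enumerate(gene_snp_counts.items()):
        for rep, snps in reps.items():
            for si, (m, p) in enumerate(snps):
                key = ("c1", gi * 1000 + si + 1)
                counts.append(SnpAlleleCount(key[0], key[1], rep, m, p, 0))
                features[key] = FeatureAssignment("exonic", (gene,))
    return counts, features


class TestPooling:
    def test_additivity_within_replicate(self):
        counts, features = make_counts({"g1": {"r1": [(10, 2), (20, 8)]}})
        rec = pool_gene_counts(counts, features)["g1"]
        assert rec.per_replicate_counts == [("r1", 30, 10)]
        assert rec.n_snps == 2

    def test_snp_order_is_irrelevant(self):
        counts, features = make_counts({"g1": {"r1": [(10, 2), (20, 8)]}})
        fwd = pool_gene_counts(counts, features)["g1"]
        rev = pool_gene_counts(list(reversed(counts)), features)["g1"]
        assert fwd.per_replicate_counts == rev.per_replicate_counts

    def test_non_exonic_snps_ignored(self):
        counts, features = make_counts({"g1": {"r1": [(10, 2)]}})
        features[("c1", 999)] = FeatureAssignment("intronic", ("g1",))
        counts.append(SnpAlleleCount("c1", 999, "r1", 100, 100, 0))
        rec = pool_gene_counts(counts, features)["g1"]
        assert rec.per_replicate_counts == [("r1", 10, 2)]


class TestInclusionFilter:
    def run(self, n_snps, pooled_per_rep, tpm):
        rec = GeneAseRecord(
            "g1",
            [(f"r{i}", m, p) for i, (m, p) in enumerate(pooled_per_rep)],
            n_snps=n_snps,
        )
        return gene_inclusion_filter({"g1": rec}, {"g1": tpm})

    def test_single_snp_with_pooled_depth_100_kept(self):
        assert "g1" in self.run(1, [(30, 10), (30, 10), (25, 15)], tpm=5.0)

    def test_single_snp_below_100_removed(self):
        assert self.run(1, [(20, 10), (20, 10), (15, 5)], tpm=5.0) == {}

    def test_low_tpm_removed_despite_many_snps(self):
        assert self.run(3, [(100, 100)] * 3, tpm=0.5) == {}

    def test_missing_tpm_excluded(self):
        rec = GeneAseRecord("g1", [("r1", 100, 100)], n_snps=3)
        assert gene_inclusion_filter({"g1": rec}, {}) == {}


class TestValidateGene:
    def make(self, reps):
        return GeneAseRecord(
            "g1", [(f"r{i}", m, p) for i, (m, p) in enumerate(reps)],
            n_snps=3,
        )

    def test_homogeneous_gene_validated_with_pooled_pm(self):
        rec = validate_gene(self.make([(90, 10), (45, 5), (88, 12)]), n_tests=100)
        assert rec.validated
        assert rec.p_m == pytest.approx(223 / 250)
        assert rec.category == "MB"

    def test_heterogeneous_but_agreeing_replicates_validated(self):
        # wildly different proportions, but all replicates are M and rejected
        rec = validate_gene(self.make([(1000, 0), (960, 40), (1000, 10)]), n_tests=1)
        assert min(1.0, rec.homogeneity_p) < 0.05  # genuinely heterogeneous
        assert rec.validated and rec.category == "M"

    def test_heterogeneous_disagreeing_replicates_rejected(self):
        # replicates span M / MB / B at high depth: heterogeneous + discordant
        rec = validate_gene(self.make([(990, 10), (800, 200), (520, 480)]), n_tests=1)
        assert not rec.validated
        assert rec.category is None

    def test_unrejected_pooled_test_gives_biparental(self):
        rec = validate_gene(self.make([(26, 24), (25, 25), (24, 26)]), n_tests=1)
        assert rec.validated and rec.category == "B"


class TestScaffoldAssignment:
    @pytest.mark.parametrize("counts, expected", [
        ({"chr1": 5, "chr2": 1}, "chr1"),
        ({"chr1": 3, "chr2": 3}, None),
        ({}, None),
        ({"chr1": 0, "chr2": 0}, None),
        ({"chr1": 0, "chr2": 2}, "chr2"),
    ])
    def test_majority_and_tie_rule(self, counts, expected):
        assert assign_scaffolds_to_chromosomes({"s1": counts}) == {"s1": expected}
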