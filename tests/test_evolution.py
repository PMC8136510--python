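"""Codon degeneracy, dN/dS counting and rank-based group comparisons."""

import itertools
import math

import numpy as np
import pytest

from poease.evolution import (
    CODON_TABLE,
    STOP_CODONS,
    CodingGeneModel,
    SiteCounts,
    annotate_degeneracy,
    classify_substitution,
    compute_dnds,
    coding_models_from_gff,
    count_sites,
    kruskal_wallis,
    nemenyi_posthoc,
    reverse_complement,
    tally_changes,
)
from poease.panel import DiscriminantSnp
from poease.simulate import simulate_toy_genome


def brute_force_degeneracy(codon):
    """Independent oracle: enumerate all 9 single-nucleotide mutants."""
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        syn = sum(
            CODON_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa
            for b in "ACGT" if b != codon[pos]
        )
        out.append(syn / 3)
    return tuple(out)


class TestDegeneracy:
    @pytest.mark.parametrize("codon, expected", [
        ("ATG", (0, 0, 0)),
        ("TTT", (0, 0, 1 / 3)),
        ("GGG", (0, 0, 1)),
    ])
    def test_hand_enumerated_examples(self, codon, expected):
        assert annotate_degeneracy(codon) == pytest.approx(expected)

    def test_matches_brute_force_for_all_61_sense_codons(self):
        sense = [c for c in CODON_TABLE if c not in STOP_CODONS]
        assert len(sense) == 61
        for codon in sense:
            assert annotate_degeneracy(codon) == pytest.approx(
                brute_force_degeneracy(codon), abs=1e-12
            ), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            annotate_degeneracy("TAA")

    def test_ambiguous_base_contributes_zero(self):
        assert annotate_degeneracy("ANG") == (0.0, 0.0, 0.0)


TOY_GENOME = {"c1": "ATGTTTGGGTAA"}
TOY_MODEL = CodingGeneModel("g1", "c1", "+", ((1, 12),))


class TestCountSites:
    def test_toy_gene_site_counts(self):
        n_sites, s_sites = count_sites(TOY_MODEL, TOY_GENOME)
        assert s_sites == pytest.approx(4 / 3)
        assert n_sites == pytest.approx(23 / 3)

    def test_sum_rule_three_per_codon(self, toy_genome):
        for model in toy_genome.models.values():
            n_sites, s_sites = count_sites(model, toy_genome.genome)
            cds = model.cds_sequence(toy_genome.genome)
            n_codons = len(cds) // 3 - 1  # terminal stop excluded
            assert n_sites + s_sites == pytest.approx(3 * n_codons)

    def test_minus_strand_equals_reverse_complement_plus(self):
        seq = "ATGTTTGGGTAA"
        genome = {"p": seq, "m": reverse_complement(seq)}
        plus = CodingGeneModel("gp", "p", "+", ((1, 12),))
        minus = CodingGeneModel("gm", "m", "-", ((1, 12),))
        assert count_sites(plus, genome) == pytest.approx(count_sites(minus, genome))

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            count_sites(CodingGeneModel("g", "c", "+", ((1, 9),)),
                        {"c": "ATGTAATTT"})


class TestClassifySubstitution:
    def test_synonymous_third_position(self):
        snp = DiscriminantSnp("c1", 6, "T", "C")  # TTT -> TTC, both Phe
        assert classify_substitution(snp, TOY_MODEL, TOY_GENOME) == "synonymous"

    def test_nonsynonymous_first_position(self):
        snp = DiscriminantSnp("c1", 4, "T", "C")  # TTT -> CTT, Phe -> Leu
        assert classify_substitution(snp, TOY_MODEL, TOY_GENOME) == "nonsynonymous"

    def test_minus_strand_reverse_complement_substitution(self):
        # plus-strand CAT carries a minus-strand ATG codon; plus-strand T>C at
        # the codon's third genomic base makes the codon GTG (Val): nonsynonymous
        genome = {"c1": "CATCATCAT"}
        model = CodingGeneModel("g1", "c1", "-", ((1, 9),))
        snp = DiscriminantSnp("c1", 3, "T", "C")
        assert classify_substitution(snp, model, genome) == "nonsynonymous"

    def test_noncoding_position(self):
        genome = {"c1": "AAATGTTTGGGTAAAA"}
        model = CodingGeneModel("g1", "c1", "+", ((3, 14),))
        assert classify_substitution(
            DiscriminantSnp("c1", 1, "A", "G"), model, genome) == "noncoding"

    def test_reference_mismatch_is_hard_error(self):
        snp = DiscriminantSnp("c1", 6, "G", "C")  # genome has T at 6
        with pytest.raises(ValueError, match="c1:6"):
            classify_substitution(snp, TOY_MODEL, TOY_GENOME)

    def test_planted_variant_effects_recovered(self, toy_genome):
        """Every planted variant classifies to its construction-time effect."""
        for row in toy_genome.truth.itertuples(index=False):
            model = toy_genome.models[row.gene_id]
            snp = DiscriminantSnp(row.contig, int(row.position), row.ref, row.alt)
            assert classify_substitution(snp, model, toy_genome.genome) == row.effect

    def test_minus_strand_genes_match_plus_strand_construction(self):
        """Random toy genes: classifying on a minus-strand gene equals
        classifying the reverse-complemented plus-strand equivalent."""
        rng = np.random.default_rng(17)
        toy = simulate_toy_genome(n_genes=100, codons_per_gene=20,
                                  n_variants=100, seed=23)
        checked = 0
        for row in toy.truth.itertuples(index=False):
            model = toy.models[row.gene_id]
            if model.strand == "+" or len(model.cds_intervals) != 1:
                continue
            start, end = model.cds_intervals[0]
            contig_seq = toy.genome[model.contig]
            flipped_genome = {"f": reverse_complement(contig_seq)}
            L = len(contig_seq)
            flipped_model = CodingGeneModel(
                "f", "f", "+", ((L - end + 1, L - start + 1),))
            flipped_snp = DiscriminantSnp(
                "f", L - int(row.position) + 1,
                reverse_complement(row.ref), reverse_complement(row.alt))
            snp = DiscriminantSnp(row.contig, int(row.position), row.ref, row.alt)
            assert classify_substitution(snp, model, toy.genome) == \
                classify_substitution(flipped_snp, flipped_model, flipped_genome)
            checked += 1
        assert checked >= 10


class TestDnds:
    def test_toy_gene_worked_example(self):
        counts = SiteCounts("g1", n_sites=23 / 3, s_sites=4 / 3,
                            n_changes=1, s_changes=1)
        assert compute_dnds(counts) == pytest.approx(12 / 69)

    def test_zero_nonsynonymous_changes_give_zero(self):
        counts = SiteCounts("g1", 7.0, 2.0, n_changes=0, s_changes=3)
        assert compute_dnds(counts) == 0.0

    def test_zero_synonymous_changes_undefined(self):
        counts = SiteCounts("g1", 7.0, 2.0, n_changes=3, s_changes=0)
        assert compute_dnds(counts) is None

    def test_tally_changes_end_to_end(self):
        panel = [DiscriminantSnp("c1", 6, "T", "C"),   # synonymous
                 DiscriminantSnp("c1", 4, "T", "C")]   # nonsynonymous
        counts = tally_changes(TOY_MODEL, TOY_GENOME, panel)
        assert (counts.n_changes, counts.s_changes) == (1, 1)
        assert counts.dnds == pytest.approx(12 / 69)


class TestKruskalWallis:
    def test_hand_computed_rank_sums(self):
        h, df, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)
        assert df == 2

    def test_identical_groups_give_zero(self):
        h, df, p = kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_invariant_to_group_order(self):
        groups = [[1, 5, 9], [2, 2, 7], [3, 8]]
        h1, *_ = kruskal_wallis(groups)
        h2, *_ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)


class TestNemenyi:
    def test_identical_groups_give_unit_pvalue(self):
        table = nemenyi_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert table[("a", "b")] == pytest.approx(1.0, abs=0.05)

    def test_larger_rank_separation_gives_smaller_p(self):
        table = nemenyi_posthoc({"A": [1, 2, 3], "B": [7, 8, 9], "C": [4, 5, 6]})
        assert table[("A", "B")] < table[("A", "C")]

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(size=n).tolist()
                  for k, n in zip("abc", (5, 9, 7))}
        table = nemenyi_posthoc(groups)
        for i, j in itertools.product("abc", repeat=2):
            assert table[(i, j)] == table[(j, i)]
            assert 0.0 <= table[(i, j)] <= 1.0
        assert all(table[(k, k)] == 1.0 for k in "abc")

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            nemenyi_posthoc({"a": [1.0], "b": []})


def test_coding_models_from_gff(tmp_path, toy_genome):
    out = tmp_path / "toy"
    toy_genome.write(out)
    models = coding_models_from_gff(out / "genes.gff3")
    assert set(models) == set(toy_genome.models)
    for gene_id, model in models.items():
        ref = toy_genome.models[gene_id]
        assert model.strand == ref.strand
        assert tuple(sorted(model.cds_intervals)) == tuple(sorted(ref.cds_intervals))
        assert model.cds_sequence(toy_genome.genome) == \
            ref.cds_sequence(toy_genome.genome)
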