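"""Per-gene dN/dS from a toy genome and rate comparison across groups.

A toy coding genome with planted variants is generated; synonymous and
nonsynonymous sites are counted from per-nucleotide codon degeneracy,
changes are classified by substituting the alternate allele into its codon,
and dN/dS = (Nd/N)/(Sd/S) is computed per gene. Groups of dN/dS values are
then compared with a Kruskal-Wallis test and a Nemenyi post hoc test.
"""

import numpy as np

from poease import kruskal_wallis, nemenyi_posthoc, simulate_toy_genome, tally_changes

toy = simulate_toy_genome(n_genes=12, codons_per_gene=60, n_variants=80, seed=5)
for gene_id in list(toy.models)[:3]:
    counts = tally_changes(toy.models[gene_id], toy.genome, toy.panel)
    ratio = counts.dnds
    print(f"{gene_id}: N={counts.n_sites:.2f} S={counts.s_sites:.2f} "
          f"Nd={counts.n_changes} Sd={counts.s_changes} "
          f"dN/dS={'undefined' if ratio is None else f'{ratio:.3f}'}")

# simulated dN/dS distributions: one group under relaxed constraint
rng = np.random.default_rng(5)
groups = {
    "B": rng.lognormal(-1.0, 0.5, 40),    # faster-evolving biparental genes
    "MB": rng.lognormal(-1.8, 0.5, 120),
    "M": rng.lognormal(-1.8, 0.5, 60),
}
h, df, p = kruskal_wallis(groups)
print(f"Kruskal-Wallis: H={h:.2f}, df={df}, p={p:.2g}")
pairwise = nemenyi_posthoc(groups)
for pair in [("B", "MB"), ("B", "M"), ("MB", "M")]:
    print(f"  Nemenyi {pair[0]} vs {pair[1]}: p={pairwise[pair]:.3g}")
# the biparental group drives the difference; the two maternally skewed
# groups do not differ from each other
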