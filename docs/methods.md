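# Methods

This note documents the statistical model behind `poease`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Background and model

In paternal genome elimination (PGE), males develop from fertilised eggs
but silence and later eliminate the paternally inherited chromosomes. The
analysis quantifies this silencing gene by gene. Reads from an F1 male are
assigned to a parental genome at *discriminant SNPs* — sites fixed for
different alleles in the two parental lines. For gene *g* with pooled
maternal count *m* and paternal count *p* over its exonic SNPs, the
maternal expression fraction is

    p_m = m / (m + p),

and the per-replicate sampling model is binomial (beta-binomial under
overdispersion). Mendelian biparental expression corresponds to
p_m = 0.5; full paternal silencing to p_m = 1.

### Panel construction

Variant records must strictly exceed DP 10, SAF/SAR 2 and RPR/RPL 1
(depth, per-strand alternate observations, per-read-side alternate
placements) and be single-nucleotide. Discriminant sites are monomorphic
reference in line A and monomorphic for one alternate in line B; panels
between conspecific lines additionally require per-line depth > 10. The
confidence filter keeps a site only if AO ≥ 20 *and* AO/DP ≥ 0.99 — either
failing condition removes it, which is the reading that yields a
high-confidence panel. Multi-allelic records are decomposed to biallelic
ones at parse time; indels and MNPs are dropped. Coordinates are 1-based
inclusive everywhere; interval-tree internals convert at the boundary.
Masking replaces each panel position with `N` and never changes sequence
length or contig count.

### SNP-level filters

A SNP enters the gene analysis only if, in *every* biological replicate,
it is observed at total depth ≥ 30 (hybrid crosses) or ≥ 20 (intraspecific
crosses, where discriminant sites are scarcer), with
(maternal+paternal)/total ≥ 0.90. The depth rule applies to *total* depth
(all reads at the site), so the 90% rule has independent effect. The
purity filter removes sites where pure maternal-line males show < 95%
reference alleles — evidence of residual within-line polymorphism; sites
absent from the pure-line control are retained (only observed impurity
removes a site) and flagged for audit. Technical replicates are assumed
merged upstream; the package sees biological replicates only. A SNP
overlapping exons of two genes is pooled into both and flagged
(`FeatureAssignment.ambiguous`), since dropping it would silently lose
signal; `pool_gene_counts(include_ambiguous=False)` excludes them instead.

### Gene-level classification

Genes covered by a single SNP are kept only if their depth pooled across
replicates is ≥ 100 (the pooled reading, applied inclusively); genes with
mean TPM < 1 are dropped. Each replicate gets a two-sided exact binomial
test of p_m = 0.5 — computed by doubling the smaller tail and capping at
1, which at a symmetric null equals minimum-likelihood summation — with
Bonferroni correction at family size = number of genes passing inclusion
in the data set, α = 0.05. Categories:

| category | rule |
|---|---|
| B  | null not rejected, **or** 0.35 ≤ p_m ≤ 0.65 |
| M  | rejected and p_m ≥ 0.95 |
| MB | rejected and 0.65 < p_m < 0.95 |
| PB | rejected and 0.05 < p_m < 0.35 |
| P  | rejected and p_m ≤ 0.05 |

The biparental rule is evaluated first, so an un-rejected gene is B
regardless of p_m; with rejection the intervals partition [0,1] (B closed,
MB/PB open, M/P closed at 0.95/0.05). Replicate consistency uses a G-test
of homogeneity on the 2×k allele-by-replicate table,
G = 2·Σ O·ln(O/E) with 0·ln 0 = 0 and df = k−1, Bonferroni-corrected at
the same family size. Homogeneous genes validate immediately;
heterogeneous genes validate only if all replicates agree on both category
and binomial significance. Validated genes are classified on
count-weighted pooled p_m with a final pooled binomial test (the pooled
test thus determines the final rejection status — whether it may overturn
a replicate-consistent category is not otherwise constrained, and
classifying on the pooled quantities is the self-consistent choice). No
Williams or Yates correction is applied to any G-test.

### Reciprocal crosses

Only genes validated in both directions of a cross pair are analysed
further. The pair threshold D is the mean absolute reciprocal p_m
difference over all paired genes, computed before any flagging. A gene is
flagged `no_poe_bias` iff its two directions disagree in category *and*
its own reciprocal difference exceeds D — both conditions, so agreeing
categories are never flagged however small D is. Unflagged genes are
classified on the unweighted mean of the two directional p_m values, with
rejection from a binomial test on counts pooled over both directions.
Across cross pairs, a gene's per-pair means are averaged unweighted and
the flag propagates conservatively (flagged anywhere ⇒ flagged in the
combination); the combination rule across pairs is a package choice, as
category conflicts between pairs have no prescribed resolution.

### Sex-specificity and expression models

SPM maps male/female expression (m, f) to [0,1] with 0 = fully
male-specific and 1 = fully female-specific. The default is the standard
squared-proportion specificity metric f²/(m²+f²); the simple proportion
f/(m+f) is available by flag — both honour the endpoint conventions, and
the squared form is the field's usual SPM definition. The expression-level
model is OLS of ln TPM on p_m + p_m² (genes with TPM = 0 excluded rather
than offset). The sex-specificity model is a quasibinomial GLM (logit
link, variance φ·μ(1−μ)) of SPM on p_m + p_m², fitted by IRLS with φ
estimated as Pearson χ²/df. Per-term F statistics are sequential (type-I,
p_m before p_m²): deviance reduction divided by φ on (1, n−3) df, matching
conventional analysis-of-deviance output. An optional TPM ≥ 10 / ≥ 100
refit guards against background expression of the other sex's genes.

### Molecular evolution

dN/dS uses unweighted per-site counting under the standard nuclear code:
each coding position contributes as synonymous sites the fraction of its
3 single-nucleotide changes that preserve the amino acid (stop-creating
changes are nonsynonymous), summed over non-stop codons; the terminal
stop is excluded and an internal stop excludes the gene. One transcript
per gene (longest total CDS). Changes are panel SNPs substituted into
their codon (reverse-complemented for minus-strand genes) and compared by
translation; all panel SNPs in a CDS are counted without polarisation.
dN/dS = (Nd/N)/(Sd/S), left *undefined* (not zero-padded) when Sd = 0 or a
site count is 0 — a 0.001 constant is appropriate only for log-scale
plotting, never for analysis. Equal mutation weights are used (no
transition/transversion weighting), the simplest per-nucleotide
degeneracy summation. No multiple-hit correction is applied; between
recently diverged lines the raw proportions are the intended statistic.
Rates across categories are compared with the tie-corrected
Kruskal–Wallis H (df = k−1) and an all-pairs Nemenyi post hoc test in the
chi-square approximation — valid for unequal group sizes, which ASE
categories always have; the tie-corrected statistic
(R̄_i−R̄_j)²/[C·N(N+1)/12·(1/n_i+1/n_j)] is referred to χ²(k−1).

Scaffolds are placed on chromosomes by majority vote over alignment
counts; ties and zero evidence leave a scaffold unassigned.

## Synthetic data: what it emulates, and not

`simulate_cross` draws each gene's true maternal fraction θ uniformly
within its category's p_m interval, from a category mixture whose default
is the somatic distribution observed in PGE males (B 5.3%, MB 68.6%,
M 25.7%, PB 0.4%, P 0.03%); 10% of genes are line-of-origin by default
(allelic divergence is common between isofemale lines, and the flagging
rule needs a realistic contaminant class to be exercised). SNPs per gene
are Poisson with mean 7 (truncated ≥ 1), within the 6.8–14.7 SNPs/gene
range such designs yield; per-SNP depth is negative-binomial with mean
500× and shape 10 (deep RNA-seq at discriminant sites); allele counts are
beta-binomial with ρ = 0.01 — real ASE counts are overdispersed, and the
classifier's robustness must be testable, with ρ = 0 recovering pure
binomial sampling. Three biological replicates per direction; gene-level
truth (θ, effect type, SNP layout, expression) depends only on the
scenario seed and is shared between directions, while count noise is
direction-specific. TPM values are log-normal around 50 so the TPM ≥ 1
filter rarely binds. All samplers derive from the single configured seed
(default 42).

The generator does **not** emulate read-level artefacts: mapping bias,
double-counting of overlapping mates, allele-specific mapping loss, PCR
duplicates, or genotyping error in the panel. Passing recovery tests
therefore demonstrates correctness of the statistical pipeline under its
sampling model, not robustness to alignment artefacts — those are exactly
what the pseudogenome masking and the 90%/95% filters address on real
data, and their effectiveness cannot be established from simulations of
this kind.

`simulate_toy_genome` builds one gene per contig (flanks, optional 20-bp
intron, both strands) with planted variants whose effect is recorded at
construction time by direct codon translation, giving an independent truth
for the substitution classifier. `simulate_sex_expression` draws genes
from male-specific / female-specific / shared components to mimic the
extreme bimodality of sex-biased expression in sexually dimorphic insects.

## Problem sizes and numerical choices

The calibration scenario used by the tests and the reproduction script is
2,000 genes × ~7 SNPs × 3 replicates × 2 directions at mean depth 500×
(ρ = 0.01) — large enough that recovery rates are stable to a fraction of
a percent, and it runs in a few seconds. Type-I calibration of
Kruskal–Wallis uses 2,000 null data sets of three n = 25 normal samples.
Binomial tails come from `scipy.stats.binom`; G-statistics guard 0·ln 0;
the GLM caps at 200 IRLS iterations and reports a trace on
non-convergence; a perfectly fitted GLM (zero dispersion) yields NaN F
statistics rather than a spurious rejection. Scaffold assignment treats
all-zero counts as no evidence. Degenerate homogeneity tables (an allele
absent everywhere) return G = 0: proportions are trivially homogeneous.

## Known limitations

* Bonferroni families are per data set (per tissue or genotype group);
  no cross-data-set multiplicity control is attempted.
* The single-transcript (longest-CDS) rule ignores isoform-specific ASE.
* `no_poe_bias` flagging depends on the pair-average threshold D, which is
  itself data-dependent; with very few paired genes D is noisy.
* dN/dS counting assumes at most one substitution per site between the
  lines compared (appropriate at small divergence, biased downward at
  large divergence).
* The quasibinomial GLM treats per-gene SPM values as independent
  observations; correlated expression between genes is not modelled.
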