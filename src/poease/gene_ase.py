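"""Gene-level allele-specific expression: pooling, testing, categories.

For each gene, maternal and paternal read counts are pooled across all its
exonic discriminant SNPs within each biological replicate, and the maternal
expression fraction

    p_m = maternal / (maternal + paternal)

is estimated. Genes are then assigned to one of five ASE categories:

    M   exclusively maternal     p_m >= 0.95
    MB  maternally biased        0.65 < p_m < 0.95
    B   biparental               test not rejected, or 0.35 <= p_m <= 0.65
    PB  paternally biased        0.05 < p_m < 0.35
    P   exclusively paternal     p_m <= 0.05

where "rejected" refers to a Bonferroni-corrected two-sided exact binomial
test against Mendelian expression (p_m = 0.5). The biparental rule takes
precedence: a gene whose null is not rejected is B regardless of p_m.

Replicate consistency is enforced with a per-gene G-test of homogeneity
(allele x replicate): homogeneous genes are validated immediately;
significantly heterogeneous genes are validated only if every replicate
agrees on both the ASE category and the significance of its binomial test.
Validated genes receive a pooled p_m (counts pooled over replicates) and a
final exact binomial test on the pooled counts.

The module also provides the G-test of independence used for category
contingency tables and the majority-vote scaffold-to-chromosome assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .counts import FeatureAssignment, SnpAlleleCount, SnpKey

logger = logging.getLogger(__name__)

CATEGORIES = ("M", "MB", "B", "PB", "P")


@dataclass
class GeneAseRecord:
    """Per-gene pooled allele counts, test results and ASE category."""

    gene_id: str
    per_replicate_counts: list[tuple[str, int, int]]  # (replicate, maternal, paternal)
    n_snps: int
    pooled_maternal: int = 0
    pooled_paternal: int = 0
    p_m: float = float("nan")
    binomial_p: float = float("nan")
    bonferroni_significant: bool = False
    homogeneity_G: float = float("nan")
    homogeneity_p: float = float("nan")
    category: str | None = None
    mean_tpm: float = float("nan")
    validated: bool = False

    @property
    def pooled_total(self) -> int:
        return self.pooled_maternal + self.pooled_paternal


def pool_gene_counts(
    snp_counts: Iterable[SnpAlleleCount],
    features: Mapping[SnpKey, FeatureAssignment],
    include_ambiguous: bool = True,
) -> dict[str, GeneAseRecord]:
    """Pool maternal/paternal counts over exonic SNPs, per gene and replicate.

    Only exonic SNPs contribute. A SNP overlapping exons of several genes
    is pooled into each of them (flagged upstream); set
    ``include_ambiguous=False`` to drop such SNPs instead. ``n_snps`` is the
    number of distinct exonic SNP positions contributing to the gene.
    """
    sums: dict[str, dict[str, list[int]]] = {}
    snps_per_gene: dict[str, set[SnpKey]] = {}
    for c in snp_counts:
        fa = features.get(c.key)
        if fa is None or fa.feature_class != "exonic":
            continue
        if fa.ambiguous and not include_ambiguous:
            continue
        for gene_id in fa.gene_ids:
            rep_sums = sums.setdefault(gene_id, {})
            m_p = rep_sums.setdefault(c.replicate_id, [0, 0])
            m_p[0] += c.maternal_count
            m_p[1] += c.paternal_count
            snps_per_gene.setdefault(gene_id, set()).add(c.key)

    records: dict[str, GeneAseRecord] = {}
    for gene_id in sorted(sums):
        per_rep = [
            (rep, m, p) for rep, (m, p) in sorted(sums[gene_id].items())
        ]
        records[gene_id] = GeneAseRecord(
            gene_id=gene_id,
            per_replicate_counts=per_rep,
            n_snps=len(snps_per_gene[gene_id]),
        )
    return records


def gene_inclusion_filter(
    records: Mapping[str, GeneAseRecord],
    mean_tpm: Mapping[str, float],
    single_snp_min_depth: int = 100,
    min_mean_tpm: float = 1.0,
) -> dict[str, GeneAseRecord]:
    """Apply the single-SNP depth rule and the low-expression filter.

    A gene is kept iff it has >= 2 exonic SNPs, or a single SNP whose read
    depth pooled across replicates is >= ``single_snp_min_depth``; and its
    mean TPM across replicates is >= ``min_mean_tpm``. Genes with no TPM
    entry are excluded with a log entry.
    """
    kept: dict[str, GeneAseRecord] = {}
    n_snp = n_tpm = n_missing = 0
    for gene_id, rec in records.items():
        pooled = sum(m + p for _, m, p in rec.per_replicate_counts)
        if rec.n_snps < 2 and pooled < single_snp_min_depth:
            n_snp += 1
            continue
        tpm = mean_tpm.get(gene_id)
        if tpm is None or math.isnan(tpm):
            logger.warning("gene %s excluded: no TPM available", gene_id)
            n_missing += 1
            continue
        if tpm < min_mean_tpm:
            n_tpm += 1
            continue
        rec.mean_tpm = float(tpm)
        kept[gene_id] = rec
    logger.info(
        "gene_inclusion_filter: kept %d genes; removed %d single-SNP low-depth, "
        "%d low-TPM, %d missing-TPM",
        len(kept), n_snp, n_tpm, n_missing,
    )
    return kept


def exact_binomial_test(maternal: int, total: int, null_p: float = 0.5) -> float:
    """Two-sided exact binomial p-value.

    At the Mendelian null (0.5) this is the doubled smaller tail, capped at
    1 — equivalent, by symmetry, to summing all outcomes no more likely than
    the observed one.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= maternal <= total:
        raise ValueError("maternal count outside [0, total]")
    if null_p == 0.5:
        lower = stats.binom.cdf(maternal, total, 0.5)
        upper = stats.binom.sf(maternal - 1, total, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    return float(stats.binomtest(maternal, total, null_p).pvalue)


def classify_ase(p_m: float, rejected: bool) -> str:
    """Map (p_m, rejection status) to an ASE category.

    Total on p_m in [0,1]. The biparental rule is evaluated first: not
    rejected, or 0.35 <= p_m <= 0.65, gives B. The remaining intervals
    partition [0,1]: P (<=0.05), PB, MB (open), M (>=0.95).
    """
    if not 0.0 <= p_m <= 1.0:
        raise ValueError(f"p_m must lie in [0,1], got {p_m}")
    if not rejected or 0.35 <= p_m <= 0.65:
        return "B"
    if p_m >= 0.95:
        return "M"
    if p_m > 0.65:
        return "MB"
    if p_m <= 0.05:
        return "P"
    return "PB"


def _g_statistic(observed: np.ndarray) -> tuple[float, int]:
    """G = 2 * sum O*ln(O/E) with 0*ln(0)=0, over a table with positive
    marginals; returns (G, df). Zero rows/columns must be removed first."""
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(observed > 0, observed * np.log(observed / expected), 0.0)
    g = 2.0 * float(terms.sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return max(g, 0.0), df


def replicate_homogeneity(
    per_replicate: Sequence[tuple[int, int]],
) -> tuple[float, int, float]:
    """G-test of homogeneity of the maternal fraction across replicates.

    The table is allele (maternal/paternal) x replicate. Replicates with
    zero total are excluded with a log entry. Returns (G, df, p) with
    df = k - 1 over the k included replicates.
    """
    included = [(m, p) for m, p in per_replicate if m + p > 0]
    if len(included) < len(per_replicate):
        logger.warning(
            "replicate_homogeneity: %d zero-total replicate(s) excluded",
            len(per_replicate) - len(included),
        )
    if len(included) < 2:
        raise ValueError("homogeneity test needs >= 2 non-empty replicates")
    table = np.array(included, dtype=float).T  # 2 x k
    # an all-zero allele row (e.g. every replicate fully maternal) leaves
    # a degenerate table: proportions are trivially homogeneous
    table = table[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2:
        return 0.0, len(included) - 1, 1.0
    g, _ = _g_statistic(table)
    df = table.shape[1] - 1
    return g, df, float(stats.chi2.sf(g, df))


def g_test_independence(
    table: Sequence[Sequence[float]] | np.ndarray,
) -> tuple[float, int, float]:
    """G-test of independence on an r x c contingency table.

    Zero-marginal rows/columns are dropped (df adjusted, logged). Returns
    (G, df, p) with df = (r-1)(c-1) and a chi-square upper-tail p-value.
    No Williams or Yates correction is applied.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or min(observed.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    rows = observed.sum(axis=1) > 0
    cols = observed.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning(
            "g_test_independence: dropped %d zero row(s), %d zero column(s)",
            int((~rows).sum()), int((~cols).sum()),
        )
        observed = observed[rows][:, cols]
        if min(observed.shape) < 2:
            raise ValueError("table degenerate after dropping zero marginals")
    g, df = _g_statistic(observed)
    return g, df, float(stats.chi2.sf(g, df))


def validate_gene(
    record: GeneAseRecord,
    n_tests: int,
    alpha: float = 0.05,
) -> GeneAseRecord:
    """Validate replicate consistency and finalise the gene's classification.

    Bonferroni correction uses family size ``n_tests`` (the number of genes
    tested in the data set) at level ``alpha``, for both the per-replicate
    binomial tests and the homogeneity G-test. The gene is validated iff
    the corrected homogeneity p-value is non-significant, OR every replicate
    agrees on ASE category and binomial-test significance. Validated genes
    get pooled counts, pooled p_m, a final exact binomial test on the pooled
    counts, and a category from the pooled quantities; non-validated genes
    are returned with ``validated=False`` and no category.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    reps = [(m, p) for _, m, p in record.per_replicate_counts if m + p > 0]

    per_rep_cat: list[str] = []
    per_rep_sig: list[bool] = []
    for m, p in reps:
        pval = exact_binomial_test(m, m + p)
        sig = min(1.0, pval * n_tests) < alpha
        per_rep_sig.append(sig)
        per_rep_cat.append(classify_ase(m / (m + p), sig))

    if len(reps) >= 2:
        g, _, p_h = replicate_homogeneity(reps)
    else:
        g, p_h = 0.0, 1.0
    record.homogeneity_G = g
    record.homogeneity_p = p_h
    homogeneous = min(1.0, p_h * n_tests) >= alpha
    agree = len(set(per_rep_cat)) == 1 and len(set(per_rep_sig)) == 1
    record.validated = homogeneous or agree

    record.pooled_maternal = sum(m for m, _ in reps)
    record.pooled_paternal = sum(p for _, p in reps)
    if record.pooled_total > 0:
        record.p_m = record.pooled_maternal / record.pooled_total
        record.binomial_p = exact_binomial_test(
            record.pooled_maternal, record.pooled_total
        )
        record.bonferroni_significant = (
            min(1.0, record.binomial_p * n_tests) < alpha
        )
    if record.validated and record.pooled_total > 0:
        record.category = classify_ase(record.p_m, record.bonferroni_significant)
    else:
        record.category = None
    return record


def classify_direction(
    snp_counts: Iterable[SnpAlleleCount],
    features: Mapping[SnpKey, FeatureAssignment],
    mean_tpm: Mapping[str, float],
    alpha: float = 0.05,
    single_snp_min_depth: int = 100,
    min_mean_tpm: float = 1.0,
) -> dict[str, GeneAseRecord]:
    """Full gene-level pass for one cross direction.

    Pools exonic SNP counts, applies inclusion filters, then runs the
    replicate-validation and pooled classification with the Bonferroni
    family set to the number of included genes. Returns validated genes.
    """
    pooled = pool_gene_counts(snp_counts, features)
    included = gene_inclusion_filter(
        pooled, mean_tpm,
        single_snp_min_depth=single_snp_min_depth, min_mean_tpm=min_mean_tpm,
    )
    n_tests = max(len(included), 1)
    validated = {}
    for gene_id, rec in included.items():
        rec = validate_gene(rec, n_tests=n_tests, alpha=alpha)
        if rec.validated:
            validated[gene_id] = rec
    logger.info(
        "classify_direction: %d/%d genes validated", len(validated), len(included)
    )
    return validated


def assign_scaffolds_to_chromosomes(
    alignment_counts: Mapping[str, Mapping[str, int]],
) -> dict[str, str | None]:
    """Majority-vote scaffold → chromosome assignment.

    Each scaffold goes to the chromosome with the most alignments; ties
    between two or more chromosomes, or no alignments at all, leave it
    unassigned (``None``).
    """
    out: dict[str, str | None] = {}
    for scaffold, per_chrom in alignment_counts.items():
        positive = {c: n for c, n in per_chrom.items() if n > 0}
        if not positive:
            out[scaffold] = None
            continue
        best = max(positive.values())
        winners = [c for c, n in positive.items() if n == best]
        out[scaffold] = winners[0] if len(winners) == 1 else None
    return out
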