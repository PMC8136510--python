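"""Reciprocal-cross combination: parent-of-origin vs line-of-origin effects.

A maternal bias observed in a single cross cannot distinguish genomic
imprinting (the bias follows the *parent* of origin) from allelic
divergence between the parental lines (the bias follows the *line* of
origin). Reciprocal crosses separate the two: a true parent-of-origin
effect shows the same maternal fraction p_m in both cross directions,
whereas a line-of-origin effect flips (p_m in one direction, approximately
1 - p_m in the other).

Genes present in both directions of a cross pair get a reciprocal-averaged
p_m and a final category; genes whose directions disagree in category *and*
whose reciprocal p_m difference exceeds the pair's average difference D are
flagged ``no_poe_bias`` (no true parent-of-origin effect). Per-pair results
can then be combined across cross pairs by averaging p_m per gene.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .gene_ase import GeneAseRecord, classify_ase, exact_binomial_test

logger = logging.getLogger(__name__)

NO_POE_BIAS = "no_poe_bias"


@dataclass
class PoeGene:
    """Reciprocal-averaged ASE for one gene in one cross pair."""

    gene_id: str
    p_m_dir1: float
    p_m_dir2: float
    category_dir1: str
    category_dir2: str
    p_m_mean: float
    poe_category: str
    cross_pair: str = ""

    @property
    def flagged(self) -> bool:
        return self.poe_category == NO_POE_BIAS


def pair_reciprocal(
    records_dir1: Mapping[str, GeneAseRecord] | Sequence[GeneAseRecord],
    records_dir2: Mapping[str, GeneAseRecord] | Sequence[GeneAseRecord],
) -> list[tuple[GeneAseRecord, GeneAseRecord]]:
    """Inner-join validated genes on gene_id across the two directions.

    Unpaired genes are dropped with a logged count; a duplicated gene_id
    within one direction is a hard error.
    """

    def as_dict(records) -> dict[str, GeneAseRecord]:
        if isinstance(records, Mapping):
            return dict(records)
        out: dict[str, GeneAseRecord] = {}
        for rec in records:
            if rec.gene_id in out:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} in one direction")
            out[rec.gene_id] = rec
        return out

    d1, d2 = as_dict(records_dir1), as_dict(records_dir2)
    shared = sorted(set(d1) & set(d2))
    dropped = len(d1) + len(d2) - 2 * len(shared)
    if dropped:
        logger.info("pair_reciprocal: dropped %d unpaired gene entries", dropped)
    return [(d1[g], d2[g]) for g in shared]


def classify_poe(
    pairs: Sequence[tuple[GeneAseRecord, GeneAseRecord]],
    alpha: float = 0.05,
    n_tests: int | None = None,
    cross_pair: str = "",
) -> list[PoeGene]:
    """Assign final parent-of-origin categories to reciprocally paired genes.

    The comparison threshold D is the mean absolute reciprocal p_m
    difference over all paired (validated) genes, computed before any
    flagging. A gene is flagged ``no_poe_bias`` iff its directions disagree
    in ASE category AND its own |p_m difference| exceeds D; otherwise it is
    classified on the reciprocal mean p_m, with rejection status from an
    exact binomial test on the counts pooled over both directions
    (Bonferroni family ``n_tests``, default: number of paired genes).
    """
    if not pairs:
        raise ValueError("classify_poe requires at least one paired gene")
    if n_tests is None:
        n_tests = len(pairs)
    d_threshold = sum(
        abs(r1.p_m - r2.p_m) for r1, r2 in pairs
    ) / len(pairs)

    out: list[PoeGene] = []
    for r1, r2 in pairs:
        mean_pm = (r1.p_m + r2.p_m) / 2.0
        diff = abs(r1.p_m - r2.p_m)
        if r1.category != r2.category and diff > d_threshold:
            category = NO_POE_BIAS
        else:
            m = r1.pooled_maternal + r2.pooled_maternal
            t = r1.pooled_total + r2.pooled_total
            rejected = min(1.0, exact_binomial_test(m, t) * n_tests) < alpha
            category = classify_ase(mean_pm, rejected)
        out.append(
            PoeGene(
                gene_id=r1.gene_id,
                p_m_dir1=r1.p_m,
                p_m_dir2=r2.p_m,
                category_dir1=r1.category,
                category_dir2=r2.category,
                p_m_mean=mean_pm,
                poe_category=category,
                cross_pair=cross_pair,
            )
        )
    return out


def combine_cross_pairs(poe_sets: Iterable[Sequence[PoeGene]]) -> list[PoeGene]:
    """Union genes across cross pairs.

    A gene observed in several pairs gets the unweighted mean of its
    per-pair reciprocal-mean p_m values and a category from the classifier
    thresholds on that mean (rejection taken as established by the per-pair
    tests). A ``no_poe_bias`` flag in any pair is conservative and
    propagates to the combined record.
    """
    by_gene: dict[str, list[PoeGene]] = defaultdict(list)
    for poe_set in poe_sets:
        for gene in poe_set:
            by_gene[gene.gene_id].append(gene)

    combined: list[PoeGene] = []
    for gene_id in sorted(by_gene):
        entries = by_gene[gene_id]
        if len(entries) == 1:
            combined.append(entries[0])
            continue
        mean_pm = sum(e.p_m_mean for e in entries) / len(entries)
        if any(e.flagged for e in entries):
            category = NO_POE_BIAS
        else:
            category = classify_ase(mean_pm, rejected=True)
        combined.append(
            PoeGene(
                gene_id=gene_id,
                p_m_dir1=float("nan"),
                p_m_dir2=float("nan"),
                category_dir1="+".join(e.category_dir1 for e in entries),
                category_dir2="+".join(e.category_dir2 for e in entries),
                p_m_mean=mean_pm,
                poe_category=category,
                cross_pair="+".join(e.cross_pair for e in entries),
            )
        )
    return combined
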