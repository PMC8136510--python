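"""Per-SNP allele counts: ingestion, filter cascade, feature assignment.

RNA-seq reads from an F1 male are assigned to the maternal or paternal
genome at discriminant SNPs by an external allele counter; this module
consumes the counter's per-replicate TSV output (contig, position,
refAllele, altAllele, refCount, altCount, totalCount), relabels counts as
maternal/paternal according to cross orientation, and applies the SNP-level
filter cascade:

1. a SNP must be observed with at least the design's minimum total depth in
   every biological replicate (default 30x for hybrid crosses, 20x for
   intraspecific crosses, where fewer discriminant sites exist);
2. the uniquely mapped reference+alternate fraction must be at least 90% of
   total depth in every replicate;
3. (hybrid data only) sites that look polymorphic within the maternal line —
   pure maternal-line males showing <95% reference alleles — are removed.

Surviving SNPs are assigned to annotation features (exonic / intronic /
intergenic / orphan) for gene-level pooling downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SnpKey = tuple[str, int]


@dataclass(frozen=True)
class SnpAlleleCount:
    """Maternal/paternal/other read counts at one SNP in one replicate."""

    contig: str
    position: int
    replicate_id: str
    maternal_count: int
    paternal_count: int
    other_count: int

    def __post_init__(self) -> None:
        for name in ("maternal_count", "paternal_count", "other_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_depth(self) -> int:
        return self.maternal_count + self.paternal_count + self.other_count

    @property
    def key(self) -> SnpKey:
        return (self.contig, self.position)


@dataclass(frozen=True)
class CrossDesign:
    """One cross direction: which line is mother, and its replicates."""

    maternal_line: str
    paternal_line: str
    replicate_ids: tuple[str, ...]
    min_depth: int = 30

    def __post_init__(self) -> None:
        if len(self.replicate_ids) < 1:
            raise ValueError("a design needs at least one replicate")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be positive")


FEATURE_CLASSES = ("exonic", "intronic", "intergenic", "orphan")


@dataclass(frozen=True)
class FeatureAssignment:
    """Feature class of one SNP, with gene id(s) for genic SNPs.

    ``ambiguous`` marks SNPs overlapping exons of more than one gene; these
    are assigned to every overlapped gene and flagged so downstream analyses
    can exclude them.
    """

    feature_class: str
    gene_ids: tuple[str, ...] = ()
    ambiguous: bool = False


def read_allele_counts(
    path: str | Path,
    panel: Iterable["object"],
    maternal_is_reference: bool,
    replicate_id: str | None = None,
) -> list[SnpAlleleCount]:
    """Read one replicate's allele-counter TSV, oriented to the cross.

    ``maternal_is_reference`` is True when the maternal line of the cross is
    the reference line of the pseudogenome (then refCount is the maternal
    count); otherwise ref/alt are swapped. Rows at positions absent from the
    panel are dropped with a logged count. ``other_count`` is
    totalCount − refCount − altCount.
    """
    path = Path(path)
    if replicate_id is None:
        replicate_id = path.stem
    panel_keys = {(snp.contig, snp.position) for snp in panel}
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "position", "refCount", "altCount", "totalCount"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    out: list[SnpAlleleCount] = []
    dropped = 0
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ref, alt, total = int(row.refCount), int(row.altCount), int(row.totalCount)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {row_number}") from exc
        if min(ref, alt, total) < 0 or total < ref + alt:
            raise ValueError(
                f"{path}: invalid counts at line {row_number} "
                f"(ref={ref}, alt={alt}, total={total})"
            )
        key = (str(row.contig), int(row.position))
        if key not in panel_keys:
            dropped += 1
            continue
        maternal, paternal = (ref, alt) if maternal_is_reference else (alt, ref)
        out.append(
            SnpAlleleCount(
                contig=key[0],
                position=key[1],
                replicate_id=replicate_id,
                maternal_count=maternal,
                paternal_count=paternal,
                other_count=total - ref - alt,
            )
        )
    if dropped:
        logger.info("%s: dropped %d rows at non-panel positions", path, dropped)
    return out


def filter_snp_counts(
    counts: Iterable[SnpAlleleCount],
    design: CrossDesign,
    unique_frac_min: float = 0.90,
) -> list[SnpAlleleCount]:
    """Apply the replicate-presence, depth and unique-fraction filters.

    A SNP survives iff, in *every* replicate of the design, it was observed
    with total depth >= ``design.min_depth`` and with
    (maternal+paternal)/total_depth >= ``unique_frac_min``. The result is
    independent of input order (records are regrouped by SNP).
    """
    by_snp: dict[SnpKey, dict[str, SnpAlleleCount]] = defaultdict(dict)
    seen_replicates: set[str] = set()
    for c in counts:
        by_snp[c.key][c.replicate_id] = c
        seen_replicates.add(c.replicate_id)
    absent = set(design.replicate_ids) - seen_replicates
    if absent:
        raise ValueError(
            f"replicate(s) {sorted(absent)} listed in design but absent from input"
        )

    kept: list[SnpAlleleCount] = []
    n_missing = n_depth = n_frac = 0
    for key in sorted(by_snp):
        per_rep = by_snp[key]
        if any(rep not in per_rep for rep in design.replicate_ids):
            n_missing += 1
            continue
        records = [per_rep[rep] for rep in design.replicate_ids]
        if any(r.total_depth < design.min_depth for r in records):
            n_depth += 1
            continue
        if any(
            (r.maternal_count + r.paternal_count) < unique_frac_min * r.total_depth
            for r in records
        ):
            n_frac += 1
            continue
        kept.extend(records)
    logger.info(
        "filter_snp_counts: %d SNPs kept; removed %d absent-from-replicate, "
        "%d below depth %d, %d below unique fraction %.2f",
        len(kept) // len(design.replicate_ids),
        n_missing, n_depth, design.min_depth, n_frac, unique_frac_min,
    )
    return kept


def purity_filter(
    counts: Sequence[SnpAlleleCount],
    pure_line_counts: Iterable[SnpAlleleCount],
    ref_frac_min: float = 0.95,
) -> list[SnpAlleleCount]:
    """Remove SNPs polymorphic within the maternal line.

    ``pure_line_counts`` come from pure maternal-line males mapped to the
    same pseudogenome, oriented so ``maternal_count`` is the reference
    (maternal-line) allele count. SNPs whose pure-line reference fraction is
    below ``ref_frac_min`` are removed; SNPs not covered in the pure-line
    data are retained (only observed impurity removes a site).
    """
    pure: dict[SnpKey, tuple[int, int]] = {}
    for c in pure_line_counts:
        m, t = pure.get(c.key, (0, 0))
        pure[c.key] = (m + c.maternal_count, t + c.total_depth)
    if not pure:
        logger.warning("purity_filter: empty pure-line table; input unchanged")
        return list(counts)

    impure: set[SnpKey] = set()
    for key, (m, t) in pure.items():
        if t > 0 and m < ref_frac_min * t:
            impure.add(key)
    uncovered = {c.key for c in counts} - set(pure)
    if uncovered:
        logger.info(
            "purity_filter: %d SNPs not covered in pure-line data kept (flagged)",
            len(uncovered),
        )
    kept = [c for c in counts if c.key not in impure]
    logger.info(
        "purity_filter: removed %d SNPs with pure-line reference fraction < %.2f",
        len({c.key for c in counts} & impure), ref_frac_min,
    )
    return kept


# ---------------------------------------------------------------------------
# Feature assignment


class GeneAnnotation:
    """Exon intervals grouped by gene, genes grouped by contig.

    Gene span is min(exon starts)..max(exon ends); introns are the span
    minus the exons. Built either from a GFF3/GTF file (via gffutils) or
    directly from an exon table.
    """

    def __init__(self, exons_by_gene: Mapping[str, Sequence[tuple[str, int, int]]]):
        # interval trees use half-open [start, end+1) internally;
        # public coordinates stay 1-based inclusive
        self._exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._span_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gene_id, exons in exons_by_gene.items():
            if not exons:
                continue
            contigs = {e[0] for e in exons}
            if len(contigs) != 1:
                raise ValueError(f"gene {gene_id} has exons on several contigs")
            contig = contigs.pop()
            for _, start, end in exons:
                self._exon_trees[contig].addi(start, end + 1, gene_id)
            span_start = min(e[1] for e in exons)
            span_end = max(e[2] for e in exons)
            self._span_trees[contig].addi(span_start, span_end + 1, gene_id)
        self.annotated_contigs = frozenset(self._span_trees)

    @classmethod
    def from_gff(cls, path: str | Path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True, force=True,
        )
        exons: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
        for exon in db.features_of_type("exon"):
            gene_id = _gene_of(db, exon)
            exons[gene_id].append((exon.seqid, exon.start, exon.end))
        if not exons:  # annotation with gene features only
            for gene in db.features_of_type("gene"):
                exons[gene.id].append((gene.seqid, gene.start, gene.end))
        return cls(exons)

    def classify(self, contig: str, position: int) -> FeatureAssignment:
        if contig not in self.annotated_contigs:
            return FeatureAssignment("orphan")
        exon_hits = sorted({iv.data for iv in self._exon_trees[contig][position]})
        if exon_hits:
            return FeatureAssignment(
                "exonic", tuple(exon_hits), ambiguous=len(exon_hits) > 1
            )
        span_hits = sorted({iv.data for iv in self._span_trees[contig][position]})
        if span_hits:
            return FeatureAssignment(
                "intronic", tuple(span_hits), ambiguous=len(span_hits) > 1
            )
        return FeatureAssignment("intergenic")


def _gene_of(db, feature) -> str:
    """Walk Parent links up to the top-level feature (the gene)."""
    current = feature
    while True:
        parents = list(db.parents(current, level=1))
        if not parents:
            return current.id
        current = parents[0]


def annotate_snp_features(
    snps: Iterable[SnpAlleleCount],
    annotation: GeneAnnotation,
) -> dict[SnpKey, FeatureAssignment]:
    """Assign each SNP exactly one feature class (and gene ids if genic)."""
    out: dict[SnpKey, FeatureAssignment] = {}
    for snp in snps:
        if snp.key not in out:
            out[snp.key] = annotation.classify(snp.contig, snp.position)
    return out
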