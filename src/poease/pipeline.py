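"""Pipeline orchestration: configured runs, manifests, summary tables.

``run_pipeline`` executes the full analysis on files on disk — SNP-level
filtering, feature assignment, gene-level pooling and classification per
cross direction, reciprocal combination, cross-pair merging — and writes
the result bundle (``genes_<pair>_dir<k>.tsv``, ``poe.tsv``,
``summary.json``, ``audit.log``, ``manifest.json``) into a run directory.
The manifest records input file hashes, every threshold as used, and the
package version, so that identical inputs and configuration reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .counts import CrossDesign, GeneAnnotation, annotate_snp_features, filter_snp_counts, purity_filter, read_allele_counts
from .gene_ase import GeneAseRecord, classify_direction, g_test_independence
from .panel import read_panel_tsv
from .poe import PoeGene, classify_poe, combine_cross_pairs, pair_reciprocal

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("B", "MB", "M", "PB", "P")


@dataclass(frozen=True)
class Thresholds:
    """All module thresholds, with the documented defaults."""

    min_depth_hybrid: int = 30
    min_depth_intraspecific: int = 20
    unique_frac_min: float = 0.90
    purity_ref_frac_min: float = 0.95
    single_snp_min_depth: int = 100
    min_mean_tpm: float = 1.0
    alpha: float = 0.05
    p_cut: float = 0.05
    b_low: float = 0.35
    b_high: float = 0.65
    m_cut: float = 0.95


@dataclass
class DirectionConfig:
    maternal_line: str
    paternal_line: str
    counts: list[str]  # one allele-count TSV per biological replicate
    tpm: str
    maternal_is_reference: bool


@dataclass
class PairConfig:
    name: str
    dir1: DirectionConfig
    dir2: DirectionConfig


@dataclass
class PipelineConfig:
    panel: str
    annotation: str
    pairs: list[PairConfig]
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    pure_line_counts: list[str] = field(default_factory=list)
    intraspecific: bool = True
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        pairs = [
            PairConfig(
                name=p["name"],
                dir1=DirectionConfig(**p["dir1"]),
                dir2=DirectionConfig(**p["dir2"]),
            )
            for p in raw.pop("pairs")
        ]
        return cls(thresholds=thresholds, pairs=pairs, **raw)

    def validate(self) -> None:
        paths = [self.panel, self.annotation, *self.pure_line_counts]
        for pair in self.pairs:
            for d in (pair.dir1, pair.dir2):
                paths.extend(d.counts)
                paths.append(d.tpm)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _gene_table(records: Mapping[str, GeneAseRecord]) -> pd.DataFrame:
    rows = []
    for rec in records.values():
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_snps": rec.n_snps,
                "pooled_maternal": rec.pooled_maternal,
                "pooled_paternal": rec.pooled_paternal,
                "p_m": rec.p_m,
                "binomial_p": rec.binomial_p,
                "bonferroni_significant": rec.bonferroni_significant,
                "homogeneity_G": rec.homogeneity_G,
                "homogeneity_p": rec.homogeneity_p,
                "category": rec.category,
                "mean_tpm": rec.mean_tpm,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id", ignore_index=True)


def _poe_table(genes: Sequence[PoeGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "cross_pair": g.cross_pair,
                "p_m_dir1": g.p_m_dir1,
                "p_m_dir2": g.p_m_dir2,
                "p_m_mean": g.p_m_mean,
                "category_dir1": g.category_dir1,
                "category_dir2": g.category_dir2,
                "poe_category": g.poe_category,
            }
            for g in genes
        ]
    ).sort_values("gene_id", ignore_index=True)


def summarize_categories(
    category_counts: Mapping[str, Mapping[str, int]] | Mapping[str, int],
    totals: Mapping[str, int] | int | None = None,
) -> pd.DataFrame:
    """Counts and one-decimal percentages per ASE category.

    Accepts either one data set (category → count) or several
    (data set → category → count); several data sets yield a table ready
    for a G-test of independence across them. ``totals`` optionally fixes
    the percentage denominator per data set (defaulting to the column sum,
    the usual case; an explicit total supports reporting against a stated
    number of classified genes).
    """
    first = next(iter(category_counts.values()), None)
    if not isinstance(first, Mapping):
        category_counts = {"all": category_counts}  # type: ignore[dict-item]
        if totals is not None and not isinstance(totals, Mapping):
            totals = {"all": int(totals)}
    rows = []
    for dataset, counts in category_counts.items():
        total = None
        if isinstance(totals, Mapping):
            total = totals.get(dataset)
        elif isinstance(totals, int):
            total = totals
        denom = total if total else sum(counts.values())
        for category in CATEGORY_ORDER:
            count = int(counts.get(category, 0))
            pct = round(100.0 * count / denom, 1) if denom else 0.0
            rows.append(
                {"dataset": dataset, "category": category, "count": count,
                 "percent": pct}
            )
    return pd.DataFrame(rows)


def category_contingency(summary: pd.DataFrame) -> tuple[list[str], list[list[int]]]:
    """Datasets x categories count matrix from a summary table, with
    all-zero category columns dropped."""
    pivot = summary.pivot(index="dataset", columns="category", values="count")
    pivot = pivot[[c for c in CATEGORY_ORDER if c in pivot.columns]]
    pivot = pivot.loc[:, pivot.sum(axis=0) > 0]
    return list(pivot.index), pivot.values.astype(int).tolist()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the result bundle; returns the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    audit = logging.FileHandler(out / "audit.log", mode="w")
    audit.setLevel(logging.INFO)
    audit.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("poease")
    root.addHandler(audit)
    root.setLevel(logging.INFO)

    try:
        panel = read_panel_tsv(config.panel)
        annotation = GeneAnnotation.from_gff(config.annotation)
        min_depth = (
            th.min_depth_intraspecific if config.intraspecific else th.min_depth_hybrid
        )

        pure_counts = []
        for path in config.pure_line_counts:
            pure_counts.extend(
                read_allele_counts(path, panel, maternal_is_reference=True)
            )

        poe_sets: list[list[PoeGene]] = []
        gene_tables: dict[str, pd.DataFrame] = {}
        for pair in config.pairs:
            validated: list[Mapping[str, GeneAseRecord]] = []
            for label, direction in (("dir1", pair.dir1), ("dir2", pair.dir2)):
                counts = []
                for path in direction.counts:
                    counts.extend(
                        read_allele_counts(
                            path, panel,
                            maternal_is_reference=direction.maternal_is_reference,
                        )
                    )
                design = CrossDesign(
                    direction.maternal_line,
                    direction.paternal_line,
                    tuple(Path(p).stem for p in direction.counts),
                    min_depth=min_depth,
                )
                filtered = filter_snp_counts(
                    counts, design, unique_frac_min=th.unique_frac_min
                )
                if pure_counts:
                    filtered = purity_filter(
                        filtered, pure_counts, ref_frac_min=th.purity_ref_frac_min
                    )
                features = annotate_snp_features(filtered, annotation)
                tpm = pd.read_csv(direction.tpm, sep="\t", index_col=0)
                genes = classify_direction(
                    filtered, features, tpm.mean(axis=1).to_dict(),
                    alpha=th.alpha,
                    single_snp_min_depth=th.single_snp_min_depth,
                    min_mean_tpm=th.min_mean_tpm,
                )
                validated.append(genes)
                table = _gene_table(genes)
                name = f"genes_{pair.name}_{label}.tsv"
                table.to_csv(out / name, sep="\t", index=False)
                gene_tables[f"{pair.name}/{label}"] = table

            pairs = pair_reciprocal(validated[0], validated[1])
            if pairs:
                poe_sets.append(
                    classify_poe(pairs, alpha=th.alpha, cross_pair=pair.name)
                )
            else:
                logger.warning("pair %s: no genes shared between directions", pair.name)

        combined = combine_cross_pairs(poe_sets) if poe_sets else []
        _poe_table(combined).to_csv(out / "poe.tsv", sep="\t", index=False)

        poe_categories: dict[str, int] = {}
        for gene in combined:
            poe_categories[gene.poe_category] = (
                poe_categories.get(gene.poe_category, 0) + 1
            )
        classified = {
            c: n for c, n in poe_categories.items() if c in CATEGORY_ORDER
        }
        summary_table = summarize_categories(classified) if classified else None

        summary = {
            "n_pairs": len(config.pairs),
            "genes_per_direction": {
                key: len(table) for key, table in gene_tables.items()
            },
            "n_combined_genes": len(combined),
            "poe_category_counts": dict(sorted(poe_categories.items())),
            "category_percent": (
                {
                    row["category"]: row["percent"]
                    for _, row in summary_table.iterrows()
                }
                if summary_table is not None
                else {}
            ),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        input_paths = [config.panel, config.annotation, *config.pure_line_counts]
        for pair in config.pairs:
            for d in (pair.dir1, pair.dir2):
                input_paths.extend(d.counts)
                input_paths.append(d.tpm)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "thresholds": dataclasses.asdict(th),
            "inputs": {p: _sha256(p) for p in sorted(set(input_paths))},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    finally:
        root.removeHandler(audit)
        audit.close()
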