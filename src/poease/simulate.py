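"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of a reciprocal-cross ASE experiment:
genes carry a true maternal fraction θ drawn from a mixture of imprinting
categories, each gene is covered by several discriminant SNPs, and each
SNP's allele counts in each biological replicate are drawn beta-binomially
(overdispersion ρ) at a negative-binomially distributed read depth. A
configurable fraction of genes carries a *line-of-origin* effect: their
biased allele follows the parental line, so the observed maternal fraction
flips between reciprocal cross directions — exactly the signature the
reciprocal analysis must flag as ``no_poe_bias``.

Default parameters mirror the study conditions at reduced scale: 2,000
genes, the somatic ASE-category mixture, ~7 exonic SNPs per gene, mean
depth 500x, ρ = 0.01, three biological replicates per direction.

A second generator builds toy coding genomes (FASTA + GFF3 + VCF) with
planted synonymous/nonsynonymous variants for the molecular-evolution
stage, and a third draws strongly sex-biased male/female expression tables.
All outputs are deterministic given the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CrossDesign, FeatureAssignment, SnpAlleleCount, SnpKey
from .evolution import (
    CODON_TABLE,
    STOP_CODONS,
    CodingGeneModel,
    reverse_complement,
)
from .panel import DiscriminantSnp, write_fasta

# Closed/open p_m intervals per category; open ends are shrunk by EPS so a
# drawn θ is always classified back to its own category.
EPS = 1e-9
CATEGORY_INTERVALS = {
    "M": (0.95, 1.0),
    "MB": (0.65 + EPS, 0.95 - EPS),
    "B": (0.35, 0.65),
    "PB": (0.05 + EPS, 0.35 - EPS),
    "P": (0.0, 0.05),
}

# somatic category mixture observed in hybrid males (counts 316/4089/1532/25/2)
DEFAULT_CATEGORY_PROPORTIONS = {
    "B": 316 / 5964,
    "MB": 4089 / 5964,
    "M": 1532 / 5964,
    "PB": 25 / 5964,
    "P": 2 / 5964,
}

PARENT_OF_ORIGIN = "parent_of_origin"
LINE_OF_ORIGIN = "line_of_origin"


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for a reciprocal-cross simulation."""

    n_genes: int = 2000
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    line_effect_fraction: float = 0.10
    snps_per_gene_mean: float = 7.0
    depth_mean: float = 500.0
    depth_shape: float = 10.0
    overdispersion_rho: float = 0.01
    replicates_per_direction: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions sum to {total}, not 1")
        if unknown := set(self.category_proportions) - set(CATEGORY_INTERVALS):
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if self.replicates_per_direction < 1:
            raise ValueError("need >= 1 replicate per direction")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    theta: float
    effect_type: str
    true_category: str


@dataclass
class SimulatedCross:
    """One cross direction: oriented counts, expression, and ground truth."""

    direction: int
    design: CrossDesign
    truth: list[SimTruth]
    panel: list[DiscriminantSnp]
    features: dict[SnpKey, FeatureAssignment]
    snp_counts: dict[str, list[SnpAlleleCount]]  # replicate -> maternal-oriented
    tpm: pd.DataFrame  # genes x replicates
    raw_tables: dict[str, pd.DataFrame]  # replicate -> allele-counter TSV dialect

    @property
    def maternal_is_reference(self) -> bool:
        return self.direction == 1

    @property
    def mean_tpm(self) -> dict[str, float]:
        return self.tpm.mean(axis=1).to_dict()

    def all_snp_counts(self) -> list[SnpAlleleCount]:
        return [c for counts in self.snp_counts.values() for c in counts]

    def write(self, outdir: str | Path) -> None:
        """Emit the TSV dialects consumed by the rest of the package."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .panel import write_panel_tsv

        write_panel_tsv(self.panel, outdir / "panel.tsv")
        for rep, table in self.raw_tables.items():
            table.to_csv(outdir / f"{rep}.tsv", sep="\t", index=False)
        self.tpm.rename_axis("gene_id").to_csv(outdir / "tpm.tsv", sep="\t")
        pd.DataFrame(
            [(t.gene_id, t.theta, t.effect_type, t.true_category) for t in self.truth],
            columns=["gene_id", "theta", "effect_type", "true_category"],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.truth:
                contig = _contig_of(t.gene_id)
                fh.write(
                    f"{contig}\tpoease-sim\tgene\t1\t{_GENE_SPAN}\t.\t+\t.\t"
                    f"ID={t.gene_id}\n"
                )
                fh.write(
                    f"{contig}\tpoease-sim\texon\t1\t{_GENE_SPAN}\t.\t+\t.\t"
                    f"ID={t.gene_id}.e1;Parent={t.gene_id}\n"
                )


_GENE_SPAN = 2000


def _contig_of(gene_id: str) -> str:
    return gene_id.replace("g", "ctg", 1)


def _draw_gene_truth(config: SimConfig) -> tuple[list[SimTruth], list[np.ndarray]]:
    """Gene-level structure shared by both directions (depends on the
    scenario seed only): θ, effect type, category, SNP positions."""
    rng = np.random.default_rng(config.seed)
    categories = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in categories])
    truth: list[SimTruth] = []
    snp_positions: list[np.ndarray] = []
    for g in range(config.n_genes):
        category = rng.choice(categories, p=probs)
        low, high = CATEGORY_INTERVALS[category]
        theta = float(rng.uniform(low, high))
        effect = (
            LINE_OF_ORIGIN
            if rng.random() < config.line_effect_fraction
            else PARENT_OF_ORIGIN
        )
        truth.append(SimTruth(f"g{g:05d}", theta, effect, category))
        n_snps = max(1, int(rng.poisson(config.snps_per_gene_mean)))
        snp_positions.append(
            np.sort(rng.choice(np.arange(1, _GENE_SPAN + 1), size=n_snps, replace=False))
        )
    return truth, snp_positions


def _beta_binomial(
    rng: np.random.Generator, depth: np.ndarray, frac: float, rho: float
) -> np.ndarray:
    if frac <= 0.0:
        return np.zeros_like(depth)
    if frac >= 1.0:
        return depth.copy()
    if rho == 0.0:
        return rng.binomial(depth, frac)
    nu = 1.0 / rho - 1.0
    p = rng.beta(frac * nu, (1.0 - frac) * nu, size=depth.shape)
    return rng.binomial(depth, p)


def simulate_cross(config: SimConfig, direction: int = 1) -> SimulatedCross:
    """Simulate one direction of a reciprocal cross.

    ``direction`` 1 makes line A (the reference line) the mother; 2 makes
    line B the mother. For parent-of-origin genes the maternal fraction is
    θ in both directions; for line-of-origin genes the line-A allele
    fraction is θ in both directions, so the *maternal* fraction flips to
    1−θ in direction 2. Gene-level truth is a function of the seed alone
    and is identical across directions; count noise is direction-specific.
    """
    if direction not in (1, 2):
        raise ValueError("direction must be 1 or 2")
    truth, snp_positions = _draw_gene_truth(config)
    rng = np.random.default_rng((config.seed, direction))

    maternal_line, paternal_line = ("A", "B") if direction == 1 else ("B", "A")
    reps = tuple(f"d{direction}r{i + 1}" for i in range(config.replicates_per_direction))
    design = CrossDesign(maternal_line, paternal_line, reps, min_depth=20)

    panel: list[DiscriminantSnp] = []
    features: dict[SnpKey, FeatureAssignment] = {}
    snp_counts: dict[str, list[SnpAlleleCount]] = {rep: [] for rep in reps}
    raw_rows: dict[str, list[tuple]] = {rep: [] for rep in reps}

    # gene-level expression, shared across directions via the scenario seed
    tpm_rng = np.random.default_rng((config.seed, 3))
    gene_tpm_mean = tpm_rng.lognormal(mean=math.log(50.0), sigma=1.0, size=config.n_genes)

    for t, positions, tpm_mean in zip(truth, snp_positions, gene_tpm_mean):
        contig = _contig_of(t.gene_id)
        # fraction of reads carrying the line-A (reference) allele
        if t.effect_type == LINE_OF_ORIGIN:
            a_frac = t.theta
        else:
            a_frac = t.theta if direction == 1 else 1.0 - t.theta
        for pos in positions:
            key = (contig, int(pos))
            panel.append(DiscriminantSnp(contig, int(pos), "A", "C"))
            features[key] = FeatureAssignment("exonic", (t.gene_id,))
            depth = rng.negative_binomial(
                config.depth_shape,
                config.depth_shape / (config.depth_shape + config.depth_mean),
                size=len(reps),
            )
            depth = np.maximum(depth, 1)
            ref = _beta_binomial(rng, depth, a_frac, config.overdispersion_rho)
            for rep, d, r in zip(reps, depth, ref):
                alt = int(d) - int(r)
                maternal, paternal = (r, alt) if direction == 1 else (alt, r)
                snp_counts[rep].append(
                    SnpAlleleCount(contig, int(pos), rep, int(maternal), int(paternal), 0)
                )
                raw_rows[rep].append((contig, int(pos), "A", "C", int(r), alt, int(d)))

    raw_tables = {
        rep: pd.DataFrame(
            rows,
            columns=[
                "contig", "position", "refAllele", "altAllele",
                "refCount", "altCount", "totalCount",
            ],
        )
        for rep, rows in raw_rows.items()
    }
    tpm = pd.DataFrame(
        {
            rep: gene_tpm_mean
            * rng.lognormal(mean=0.0, sigma=0.1, size=config.n_genes)
            for rep in reps
        },
        index=[t.gene_id for t in truth],
    )
    return SimulatedCross(
        direction=direction,
        design=design,
        truth=truth,
        panel=panel,
        features=features,
        snp_counts=snp_counts,
        tpm=tpm,
        raw_tables=raw_tables,
    )


def simulate_reciprocal(config: SimConfig) -> tuple[SimulatedCross, SimulatedCross]:
    """Both directions of the reciprocal design, sharing gene-level truth."""
    return simulate_cross(config, 1), simulate_cross(config, 2)


# ---------------------------------------------------------------------------
# Toy coding genomes for the molecular-evolution stage


@dataclass
class ToyGenome:
    """A small, mutually consistent FASTA/GFF3/VCF trio with planted
    coding variants whose effects are known by construction."""

    genome: dict[str, str]
    models: dict[str, CodingGeneModel]
    panel: list[DiscriminantSnp]
    truth: pd.DataFrame  # contig, position, gene_id, ref, alt, effect

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fasta")
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for gene_id, model in self.models.items():
                span = (
                    min(s for s, _ in model.cds_intervals),
                    max(e for _, e in model.cds_intervals),
                )
                attrs = f"ID={gene_id}"
                fh.write(
                    f"{model.contig}\tpoease-sim\tgene\t{span[0]}\t{span[1]}\t.\t"
                    f"{model.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{model.contig}\tpoease-sim\tmRNA\t{span[0]}\t{span[1]}\t.\t"
                    f"{model.strand}\t.\tID={gene_id}.t1;Parent={gene_id}\n"
                )
                for k, (start, end) in enumerate(sorted(model.cds_intervals), 1):
                    for ftype in ("exon", "CDS"):
                        fh.write(
                            f"{model.contig}\tpoease-sim\t{ftype}\t{start}\t{end}\t.\t"
                            f"{model.strand}\t0\tID={gene_id}.{ftype}{k};"
                            f"Parent={gene_id}.t1\n"
                        )
        self._write_vcf(outdir / "variants.vcf")
        self.truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)

    def _write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, seq in self.genome.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alt obs">\n')
            for key in ("SAF", "SAR", "RPR", "RPL"):
                fh.write(
                    f'##INFO=<ID={key},Number=A,Type=Integer,Description="{key}">\n'
                )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                "line_a\tline_b\n"
            )
            rows = self.truth.sort_values(["contig", "position"])
            for row in rows.itertuples(index=False):
                fh.write(
                    f"{row.contig}\t{row.position}\t.\t{row.ref}\t{row.alt}\t"
                    f"100\tPASS\tDP=100;AO=50;SAF=25;SAR=25;RPR=25;RPL=25\t"
                    f"GT:DP\t0/0:50\t1/1:50\n"
                )


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + n_codons random non-stop codons + one stop codon."""
    sense = [c for c in CODON_TABLE if c not in STOP_CODONS]
    body = "".join(rng.choice(sense) for _ in range(n_codons))
    stop = str(rng.choice(sorted(STOP_CODONS)))
    return "ATG" + body + stop


def _genomic_position(model: CodingGeneModel, cds_index: int) -> int:
    """Inverse of :meth:`CodingGeneModel.cds_index_of` (phase 0)."""
    offset = 0
    for start, end in model.cds_intervals:
        length = end - start + 1
        if cds_index < offset + length:
            within = cds_index - offset
            return end - within if model.strand == "-" else start + within
        offset += length
    raise IndexError(f"CDS index {cds_index} outside gene {model.gene_id}")


def simulate_toy_genome(
    n_genes: int = 10,
    codons_per_gene: int = 50,
    n_variants: int = 30,
    seed: int = 42,
    max_retries: int = 1000,
) -> ToyGenome:
    """Random coding genes on both strands with planted variants.

    Each gene sits on its own contig, optionally split into two CDS
    intervals by a 20-bp intron. Variants are placed at distinct positions
    inside non-stop codons; their synonymous/nonsynonymous status is
    recorded at construction time by translating the mutated codon.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    models: dict[str, CodingGeneModel] = {}
    cds_by_gene: dict[str, str] = {}
    flank = 30
    intron = 20

    for g in range(n_genes):
        gene_id = f"tg{g:03d}"
        contig = f"tctg{g:03d}"
        cds = _random_cds(rng, codons_per_gene)
        strand = "+" if rng.random() < 0.5 else "-"
        total = len(cds)
        split = bool(rng.random() < 0.5)
        random_seq = lambda n: "".join(rng.choice(list("ACGT")) for _ in range(n))
        if split:
            cut = int(rng.integers(3, total - 3))
            part1, part2 = cds[:cut], cds[cut:]
        else:
            part1, part2 = cds, ""

        if strand == "+":
            seq = random_seq(flank) + part1
            iv1 = (flank + 1, flank + len(part1))
            intervals = [iv1]
            if part2:
                seq += random_seq(intron) + part2
                intervals.append(
                    (iv1[1] + intron + 1, iv1[1] + intron + len(part2))
                )
            seq += random_seq(flank)
        else:
            # translation order = highest-coordinate interval first
            seq = random_seq(flank)
            if part2:
                seq += reverse_complement(part2)
                iv_b = (flank + 1, flank + len(part2))
                seq += random_seq(intron)
                start_a = iv_b[1] + intron + 1
            else:
                iv_b = None
                start_a = flank + 1
            seq += reverse_complement(part1)
            iv_a = (start_a, start_a + len(part1) - 1)
            seq += random_seq(flank)
            intervals = [iv_a] + ([iv_b] if iv_b else [])

        genome[contig] = seq
        models[gene_id] = CodingGeneModel(
            gene_id=gene_id,
            contig=contig,
            strand=strand,
            cds_intervals=tuple(intervals),
        )
        cds_by_gene[gene_id] = cds

    gene_ids = sorted(models)
    used: set[tuple[str, int]] = set()
    records: list[tuple] = []
    attempts = 0
    while len(records) < n_variants:
        attempts += 1
        if attempts > max_retries * max(n_variants, 1):
            raise RuntimeError(
                f"could not place {n_variants} variants without collision"
            )
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        model = models[gene_id]
        cds = cds_by_gene[gene_id]
        idx = int(rng.integers(0, len(cds) - 3))  # exclude the stop codon
        pos = _genomic_position(model, idx)
        if (model.contig, pos) in used:
            continue
        codon_i, within = divmod(idx, 3)
        codon = cds[codon_i * 3:codon_i * 3 + 3]
        alt_cds = str(rng.choice([b for b in "ACGT" if b != codon[within]]))
        mutant = codon[:within] + alt_cds + codon[within + 1:]
        effect = (
            "synonymous"
            if CODON_TABLE[mutant] == CODON_TABLE[codon]
            else "nonsynonymous"
        )
        ref_plus = genome[model.contig][pos - 1]
        alt_plus = reverse_complement(alt_cds) if model.strand == "-" else alt_cds
        used.add((model.contig, pos))
        records.append((model.contig, pos, gene_id, ref_plus, alt_plus, effect))

    truth = pd.DataFrame(
        records, columns=["contig", "position", "gene_id", "ref", "alt", "effect"]
    ).sort_values(["contig", "position"], ignore_index=True)
    toy_panel = [
        DiscriminantSnp(r.contig, int(r.position), r.ref, r.alt)
        for r in truth.itertuples(index=False)
    ]
    return ToyGenome(genome=genome, models=models, panel=toy_panel, truth=truth)


# ---------------------------------------------------------------------------
# Sex-biased expression


def simulate_sex_expression(
    n_genes: int = 1000,
    bimodality: Sequence[float] = (0.4, 0.4, 0.2),
    seed: int = 42,
    tpm_log_mean: float = math.log(50.0),
    tpm_log_sigma: float = 1.0,
) -> tuple[dict[str, float], dict[str, float], dict[str, str]]:
    """Male/female TPM tables from a three-component mixture.

    Components, in order: male-specific (female TPM 0), female-specific
    (male TPM 0) and shared (both sexes drawn i.i.d. from the same
    log-normal). Returns (male table, female table, component labels).
    """
    weights = np.asarray(bimodality, dtype=float)
    if len(weights) != 3 or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("bimodality must be 3 weights summing to 1")
    rng = np.random.default_rng(seed)
    components = rng.choice(
        ["male_specific", "female_specific", "shared"], size=n_genes, p=weights
    )
    male: dict[str, float] = {}
    female: dict[str, float] = {}
    labels: dict[str, str] = {}
    for i, comp in enumerate(components):
        gene = f"sg{i:05d}"
        expr = lambda: float(rng.lognormal(tpm_log_mean, tpm_log_sigma))
        if comp == "male_specific":
            male[gene], female[gene] = expr(), 0.0
        elif comp == "female_specific":
            male[gene], female[gene] = 0.0, expr()
        else:
            male[gene], female[gene] = expr(), expr()
        labels[gene] = str(comp)
    return male, female, labels
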