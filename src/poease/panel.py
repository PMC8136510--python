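"""Discriminant-SNP panels and pseudogenome masking.

In a cross between two (near-)homozygous parental lines, a *discriminant
SNP* is a site fixed for different alleles in the two lines, so that every
RNA-seq read covering it can be assigned to the maternally or paternally
inherited genome. This module builds such panels from variant calls, applies
the confidence filters used for panel construction, and hard-masks panel
positions in the reference with ``N`` to remove reference-allele mapping
bias (the resulting reference is called a *pseudogenome*).

Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class QualityThresholds:
    """Site-quality thresholds applied to raw variant calls.

    All comparisons are strict: a site must exceed every threshold to
    survive. Defaults follow the conventional high-confidence filter on
    FreeBayes-style annotations: total depth (DP), alternate observations on
    each strand (SAF/SAR) and alternate observations placed on each side of
    the read (RPR/RPL).
    """

    min_dp: int = 10
    min_saf: int = 2
    min_sar: int = 2
    min_rpr: int = 1
    min_rpl: int = 1


@dataclass(frozen=True)
class VariantSite:
    """One biallelic variant record with quality annotations.

    ``genotype_a``/``genotype_b`` are diploid genotypes of the two parental
    lines as pairs of allele indices (0 = reference, 1 = this alternate), or
    ``None`` when missing. ``depth_a``/``depth_b`` carry per-line read depth
    when available (required for the interline panel rule).
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    genotype_a: tuple[int, int] | None = None
    genotype_b: tuple[int, int] | None = None
    depth: int = 0
    alt_observations: int = 0
    forward_alt: int | None = None
    reverse_alt: int | None = None
    reads_right: int | None = None
    reads_left: int | None = None
    depth_a: int | None = None
    depth_b: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def is_snp(self) -> bool:
        return (
            self.ref_allele in _NUCLEOTIDES
            and self.alt_allele in _NUCLEOTIDES
            and self.ref_allele != self.alt_allele
        )


@dataclass(frozen=True)
class DiscriminantSnp:
    """A site fixed for different alleles in the maternal and paternal lines.

    ``ao``/``dp`` are carried over from the underlying variant record so the
    confidence filter can be applied to a panel directly;
    ``passed_confidence`` records whether it was.
    """

    contig: str
    position: int
    maternal_allele: str
    paternal_allele: str
    passed_confidence: bool = False
    ao: int | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError("maternal and paternal alleles must differ")


def filter_variant_quality(
    sites: Iterable[VariantSite],
    thresholds: QualityThresholds = QualityThresholds(),
) -> list[VariantSite]:
    """Keep single-nucleotide sites strictly exceeding all quality thresholds.

    Records with a missing quality field are rejected with a logged reason
    rather than raising. Input order is preserved; the operation is
    idempotent.
    """
    kept: list[VariantSite] = []
    for site in sites:
        if not site.is_snp:
            logger.debug("%s:%d rejected: not a SNP", site.contig, site.position)
            continue
        fields = {
            "SAF": (site.forward_alt, thresholds.min_saf),
            "SAR": (site.reverse_alt, thresholds.min_sar),
            "RPR": (site.reads_right, thresholds.min_rpr),
            "RPL": (site.reads_left, thresholds.min_rpl),
        }
        missing = [name for name, (value, _) in fields.items() if value is None]
        if missing:
            logger.warning(
                "%s:%d rejected: missing quality field(s) %s",
                site.contig, site.position, ",".join(missing),
            )
            continue
        if site.depth <= thresholds.min_dp:
            continue
        if all(value > cut for value, cut in fields.values()):
            kept.append(site)
    return kept


def _is_hom(genotype: tuple[int, int] | None, allele: int) -> bool:
    return genotype is not None and genotype == (allele, allele)


def select_discriminant_snps(
    sites: Iterable[VariantSite],
    mode: str = "interspecific",
    min_line_depth: int = 10,
) -> list[DiscriminantSnp]:
    """Select sites monomorphic for the reference allele in line A and for
    one alternate allele in line B.

    Line A is taken as the maternal (reference) line. Heterozygous or
    missing genotypes exclude a site silently. In ``interline`` mode (panels
    between conspecific isofemale lines) per-line depth must additionally
    exceed ``min_line_depth`` in both lines.
    """
    if mode not in ("interspecific", "interline"):
        raise ValueError(f"unknown mode {mode!r}")
    panel: list[DiscriminantSnp] = []
    seen: set[tuple[str, int]] = set()
    for site in sites:
        if not site.is_snp:
            continue
        if not (_is_hom(site.genotype_a, 0) and _is_hom(site.genotype_b, 1)):
            continue
        if mode == "interline":
            da = site.depth_a if site.depth_a is not None else site.depth
            db = site.depth_b if site.depth_b is not None else site.depth
            if not (da > min_line_depth and db > min_line_depth):
                continue
        key = (site.contig, site.position)
        if key in seen:
            logger.warning("duplicate panel position %s:%d dropped", *key)
            continue
        seen.add(key)
        panel.append(
            DiscriminantSnp(
                contig=site.contig,
                position=site.position,
                maternal_allele=site.ref_allele,
                paternal_allele=site.alt_allele,
                ao=site.alt_observations,
                dp=site.depth,
            )
        )
    return panel


def confidence_filter(
    panel: Iterable[DiscriminantSnp],
    ao_min: int = 20,
    ao_dp_min: float = 0.99,
) -> list[DiscriminantSnp]:
    """Keep only high-confidence panel sites.

    A site is kept only if AO >= ``ao_min`` and AO/DP >= ``ao_dp_min``;
    failing either criterion removes it. Sites with DP = 0 or missing
    AO/DP are removed with a log entry. Idempotent.
    """
    kept: list[DiscriminantSnp] = []
    for snp in panel:
        if snp.ao is None or snp.dp is None or snp.dp == 0:
            logger.warning(
                "%s:%d removed by confidence filter: AO/DP unavailable",
                snp.contig, snp.position,
            )
            continue
        if snp.ao < ao_min or snp.ao / snp.dp < ao_dp_min:
            continue
        kept.append(replace(snp, passed_confidence=True))
    return kept


def mask_pseudogenome(
    reference: Mapping[str, str],
    panel: Iterable[DiscriminantSnp],
) -> dict[str, str]:
    """Hard-mask every panel position with ``N``.

    Returns a new contig → sequence mapping; lengths and contig set are
    unchanged. A panel position beyond its contig's length is a hard error.
    """
    mutable = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    for snp in panel:
        if snp.contig not in mutable:
            raise KeyError(f"panel contig {snp.contig!r} absent from reference")
        seq = mutable[snp.contig]
        if snp.position > len(seq):
            raise IndexError(
                f"panel position {snp.contig}:{snp.position} beyond contig "
                f"length {len(seq)}"
            )
        seq[snp.position - 1] = ord("N")
    return {name: seq.decode("ascii") for name, seq in mutable.items()}


# ---------------------------------------------------------------------------
# I/O helpers

PANEL_COLUMNS = ("contig", "position", "maternal_allele", "paternal_allele")


def write_panel_tsv(panel: Iterable[DiscriminantSnp], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for snp in panel:
            fh.write(
                f"{snp.contig}\t{snp.position}\t{snp.maternal_allele}\t"
                f"{snp.paternal_allele}\n"
            )


def read_panel_tsv(path: str | Path) -> list[DiscriminantSnp]:
    panel: list[DiscriminantSnp] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PANEL_COLUMNS:
            raise ValueError(f"unexpected panel header {header!r} in {path}")
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{i}: expected 4 columns")
            panel.append(
                DiscriminantSnp(parts[0], int(parts[1]), parts[2], parts[3])
            )
    return panel


def variant_sites_from_vcf(
    path: str | Path,
    sample_a: str | None = None,
    sample_b: str | None = None,
) -> list[VariantSite]:
    """Parse a two-sample VCF into :class:`VariantSite` records.

    Multi-allelic records are decomposed into one biallelic record per
    alternate allele (with per-allele AO/SAF/SAR/RPR/RPL where these are
    ``A``-typed); indels and MNPs are dropped at parse time. Genotypes are
    remapped so allele index 1 means "this alternate": a genotype carrying a
    different alternate becomes missing for that decomposed record.
    """
    import pysam

    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_a is None and len(samples) >= 2:
            sample_a, sample_b = samples[0], samples[1]

        def info_per_alt(rec, key: str, i: int) -> int | None:
            val = rec.info.get(key)
            if val is None:
                return None
            if isinstance(val, tuple):
                return int(val[i]) if i < len(val) else None
            return int(val)

        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # indel/MNP
                if rec.ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                    continue

                def remap(sample: str | None) -> tuple[tuple[int, int] | None, int | None]:
                    if sample is None or sample not in rec.samples:
                        return None, None
                    fmt = rec.samples[sample]
                    gt = fmt.get("GT")
                    sdp = fmt.get("DP")
                    if gt is None or any(a is None for a in gt) or len(gt) != 2:
                        return None, sdp
                    mapped = []
                    for a in gt:
                        if a == 0:
                            mapped.append(0)
                        elif a == i + 1:
                            mapped.append(1)
                        else:
                            return None, sdp  # carries a different alternate
                    return (mapped[0], mapped[1]), sdp

                gt_a, dp_a = remap(sample_a)
                gt_b, dp_b = remap(sample_b)
                dp = rec.info.get("DP")
                sites.append(
                    VariantSite(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        genotype_a=gt_a,
                        genotype_b=gt_b,
                        depth=int(dp) if dp is not None else 0,
                        alt_observations=info_per_alt(rec, "AO", i) or 0,
                        forward_alt=info_per_alt(rec, "SAF", i),
                        reverse_alt=info_per_alt(rec, "SAR", i),
                        reads_right=info_per_alt(rec, "RPR", i),
                        reads_left=info_per_alt(rec, "RPL", i),
                        depth_a=dp_a,
                        depth_b=dp_b,
                    )
                )
    return sites


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def mask_fasta(
    fasta_in: str | Path,
    panel: Sequence[DiscriminantSnp],
    fasta_out: str | Path,
) -> None:
    """File-level convenience: read, mask and rewrite a reference FASTA."""
    write_fasta(mask_pseudogenome(read_fasta(fasta_in), panel), fasta_out)
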