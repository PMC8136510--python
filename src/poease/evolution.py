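"""Molecular evolution: codon degeneracy, dN/dS and rank-based comparisons.

The divergence-rate statistic is the unweighted counting form of dN/dS:
the number of nonsynonymous changes per nonsynonymous site divided by the
number of synonymous changes per synonymous site. Site counts come from
per-nucleotide codon degeneracy: each coding position contributes, as
synonymous sites, the fraction of its 3 possible single-nucleotide changes
that preserve the encoded amino acid (changes creating a stop codon count
as nonsynonymous), summed per gene; nonsynonymous sites are the complement
to 3 per codon. The standard nuclear genetic code is used, one transcript
per gene (the longest complete CDS), and the terminal stop codon is
excluded from the site counts. No multiple-hit correction is applied —
changes are raw counts of fixed differences falling in the CDS.

Rates are compared across ASE categories with a Kruskal–Wallis test and
an all-pairs Nemenyi post hoc test (chi-square approximation, valid for
unequal group sizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .panel import DiscriminantSnp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard nuclear code
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodingGeneModel:
    """One gene's coding model: CDS intervals in translation order.

    Intervals are 1-based inclusive genomic coordinates. For minus-strand
    genes the translation order runs from the highest-coordinate interval
    downward, and bases are read reverse-complemented. ``phase`` trims
    incomplete leading codon bases of the first interval.
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.phase <= 2:
            raise ValueError("phase must be 0..2")
        if not self.cds_intervals:
            raise ValueError(f"gene {self.gene_id}: empty CDS")

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Phase-trimmed coding sequence in translation order."""
        contig_seq = genome[self.contig]
        chunks = []
        for start, end in self.cds_intervals:
            if not 1 <= start <= end <= len(contig_seq):
                raise IndexError(
                    f"gene {self.gene_id}: CDS interval {start}-{end} outside "
                    f"contig {self.contig}"
                )
            chunk = contig_seq[start - 1:end].upper()
            chunks.append(reverse_complement(chunk) if self.strand == "-" else chunk)
        return "".join(chunks)[self.phase:]

    def cds_index_of(self, position: int) -> int | None:
        """0-based index into the phase-trimmed CDS of a genomic position,
        or None if the position is outside the CDS (or in the trimmed
        phase overhang)."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= position <= end:
                within = (end - position) if self.strand == "-" else (position - start)
                idx = offset + within - self.phase
                return idx if idx >= 0 else None
            offset += end - start + 1
        return None


@dataclass
class SiteCounts:
    """Per-gene synonymous/nonsynonymous site and change counts."""

    gene_id: str
    n_sites: float
    s_sites: float
    n_changes: int = 0
    s_changes: int = 0

    @property
    def dnds(self) -> float | None:
        return compute_dnds(self)


def annotate_degeneracy(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous fraction of a (non-stop) codon.

    For each of the 3 positions, the fraction of the 3 possible
    single-nucleotide changes that leave the amino acid unchanged; changes
    creating a stop codon are nonsynonymous. A position with an ambiguous
    base contributes 0 and is flagged in the log.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if any(b not in _BASES for b in codon):
        logger.warning("codon %s contains ambiguous base(s); degeneracy 0", codon)
        return (0.0, 0.0, 0.0)
    aa = CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"{codon} is a stop codon")
    fractions = []
    for pos in range(3):
        synonymous = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                synonymous += 1
        fractions.append(synonymous / 3.0)
    return tuple(fractions)


def count_sites(
    model: CodingGeneModel, genome: Mapping[str, str]
) -> tuple[float, float]:
    """(n_sites, s_sites) summed over the gene's non-stop codons.

    The terminal stop codon (if present) is excluded; an internal stop is a
    hard error (the caller should flag and exclude the gene from dN/dS).
    """
    cds = model.cds_sequence(genome)
    n_codons = len(cds) // 3
    if n_codons == 0:
        raise ValueError(f"gene {model.gene_id}: zero-length CDS")
    codons = [cds[i * 3:(i + 1) * 3] for i in range(n_codons)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    s_sites = 0.0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(
                f"gene {model.gene_id}: internal stop codon at codon {i + 1}"
            )
        s_sites += sum(annotate_degeneracy(codon))
    n_sites = 3.0 * len(codons) - s_sites
    return n_sites, s_sites


def classify_substitution(
    snp: DiscriminantSnp,
    model: CodingGeneModel,
    genome: Mapping[str, str],
) -> str:
    """Classify a fixed difference as synonymous / nonsynonymous / noncoding.

    The SNP's alleles are given on the plus strand; the reference
    (maternal) allele must match the genome. For minus-strand genes the
    alternate base is complemented before substitution into the codon.
    """
    if snp.contig != model.contig:
        return "noncoding"
    idx = model.cds_index_of(snp.position)
    if idx is None:
        return "noncoding"
    genome_base = genome[snp.contig][snp.position - 1].upper()
    if genome_base != snp.maternal_allele.upper():
        raise ValueError(
            f"reference mismatch at {snp.contig}:{snp.position}: genome has "
            f"{genome_base}, panel says {snp.maternal_allele}"
        )
    cds = model.cds_sequence(genome)
    codon_idx, within = divmod(idx, 3)
    codon = cds[codon_idx * 3:codon_idx * 3 + 3]
    if len(codon) < 3:
        return "noncoding"  # trailing partial codon
    alt = snp.paternal_allele.upper()
    if model.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    mutant = codon[:within] + alt + codon[within + 1:]
    return "synonymous" if CODON_TABLE[mutant] == CODON_TABLE[codon] else "nonsynonymous"


def tally_changes(
    model: CodingGeneModel,
    genome: Mapping[str, str],
    panel: Iterable[DiscriminantSnp],
) -> SiteCounts:
    """Site and change counts for one gene over a discriminant-SNP panel."""
    n_sites, s_sites = count_sites(model, genome)
    counts = SiteCounts(model.gene_id, n_sites=n_sites, s_sites=s_sites)
    for snp in panel:
        effect = classify_substitution(snp, model, genome)
        if effect == "synonymous":
            counts.s_changes += 1
        elif effect == "nonsynonymous":
            counts.n_changes += 1
    return counts


def compute_dnds(counts: SiteCounts) -> float | None:
    """dN/dS = (Nd/N) / (Sd/S); None (undefined) when Sd = 0 or a site
    count is 0 — such genes are excluded from rate comparisons."""
    if counts.s_changes == 0 or counts.s_sites == 0 or counts.n_sites == 0:
        return None
    dn = counts.n_changes / counts.n_sites
    ds = counts.s_changes / counts.s_sites
    return dn / ds


def coding_models_from_gff(path) -> dict[str, CodingGeneModel]:
    """Load one coding model per gene from GFF3/GTF: the transcript with
    the longest total CDS, intervals ordered in translation order."""
    import gffutils
    from .counts import _gene_of

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    by_transcript: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id])
        for parent in parents:
            by_transcript.setdefault(parent, []).append(cds)

    best: dict[str, CodingGeneModel] = {}
    best_len: dict[str, int] = {}
    for transcript_id, parts in by_transcript.items():
        try:
            gene_id = _gene_of(db, db[transcript_id])
        except gffutils.FeatureNotFoundError:
            gene_id = transcript_id
        strand = parts[0].strand
        intervals = sorted(
            ((p.start, p.end) for p in parts), reverse=(strand == "-")
        )
        ordered = sorted(parts, key=lambda p: p.start, reverse=(strand == "-"))
        phase = ordered[0].frame
        phase = int(phase) if phase not in (None, ".") else 0
        total = sum(end - start + 1 for start, end in intervals)
        if total > best_len.get(gene_id, 0):
            best_len[gene_id] = total
            best[gene_id] = CodingGeneModel(
                gene_id=gene_id,
                contig=parts[0].seqid,
                strand=strand,
                cds_intervals=tuple(intervals),
                phase=phase,
            )
    return best


# ---------------------------------------------------------------------------
# Rank-based group comparisons


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected), df = k−1, chi-square p-value.

    Invariant to group order. All-identical values give H = 0, p = 1.
    """
    samples = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    df = len(samples) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def nemenyi_posthoc(
    groups: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], float]:
    """All-pairs Nemenyi post hoc test, chi-square approximation.

    For groups i, j with mean ranks R̄ over the pooled sample of size N:

        chi2_ij = (R̄_i − R̄_j)^2 / [ C · N(N+1)/12 · (1/n_i + 1/n_j) ]

    with tie correction C = 1 − Σ(t^3 − t)/(N^3 − N), referred to the
    chi-square distribution with k−1 degrees of freedom. Valid for unequal
    group sizes. Returns a symmetric mapping with unit diagonal.
    """
    names = list(groups)
    samples = [np.asarray(groups[name], dtype=float) for name in names]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    sizes = np.array([len(s) for s in samples])
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size

    _, tie_counts = np.unique(pooled, return_counts=True)
    c = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n_total**3 - n_total)
    df = len(names) - 1
    base = n_total * (n_total + 1) / 12.0

    out: dict[tuple[str, str], float] = {}
    for i, name_i in enumerate(names):
        out[(name_i, name_i)] = 1.0
        for j in range(i + 1, len(names)):
            name_j = names[j]
            denom = c * base * (1.0 / sizes[i] + 1.0 / sizes[j])
            if denom == 0 or c == 0:  # all values tied
                p = 1.0
            else:
                chi2 = (mean_ranks[i] - mean_ranks[j]) ** 2 / denom
                p = float(stats.chi2.sf(chi2, df))
            out[(name_i, name_j)] = p
            out[(name_j, name_i)] = p
    return out
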