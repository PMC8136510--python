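"""Build a discriminant-SNP panel from parental variant calls and hard-mask
it into a pseudogenome.

A toy genome with planted fixed differences between two parental lines is
generated, the variant records are filtered and the monomorphic
ref-vs-alt sites selected, and the reference is N-masked at the panel
positions so that neither parental allele enjoys a mapping advantage.
"""

import tempfile
from pathlib import Path

from poease import (
    filter_variant_quality,
    mask_pseudogenome,
    select_discriminant_snps,
    simulate_toy_genome,
)
from poease.panel import variant_sites_from_vcf

out = Path(tempfile.mkdtemp())
toy = simulate_toy_genome(n_genes=4, codons_per_gene=30, n_variants=12, seed=1)
toy.write(out)

sites = variant_sites_from_vcf(out / "variants.vcf", "line_a", "line_b")
sites = filter_variant_quality(sites)
panel = select_discriminant_snps(sites, mode="interspecific")
print(f"{len(sites)} variant records -> {len(panel)} discriminant SNPs")

masked = mask_pseudogenome(toy.genome, panel)
n_masked = sum(seq.count("N") for seq in masked.values())
print(f"pseudogenome: {len(masked)} contigs, {n_masked} positions hard-masked")
# every panel position is now N, so reads carrying either parental allele
# mismatch the reference equally at these sites
first = panel[0]
print(f"example: {first.contig}:{first.position} "
      f"{first.maternal_allele}/{first.paternal_allele} -> "
      f"{masked[first.contig][first.position - 1]}")
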