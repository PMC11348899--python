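"""Annotate DMR locations and associate them with gene regulatory regions.

Each called DMR gets one of eight transcript-anchored location
categories (Upstream, Body, Whole-body, Intergenic, ...) and, under the
50%-overlap rule, links to gene promoter / downstream windows.  Planted
promoter DMRs should annotate as Upstream and associate with their host
gene's upstream regulatory region.
"""

import dataclasses

from methdriver import annotate, dmr
from methdriver.simulate import (
    SimConfig, choose_spread_genes, generate_genome, generate_methylome,
    plant_promoter_dmrs,
)

cfg = SimConfig(seed=4, n_chromosomes=2, chrom_length_bp=1_000_000,
                n_cpgs_per_chrom=600, n_genes=16)
genome = generate_genome(cfg)
hosts = choose_spread_genes(genome, 4)
planted = plant_promoter_dmrs(genome, hosts, +30.0)
cfg = dataclasses.replace(cfg, planted_dmrs=tuple(planted))
matrix, sheet = generate_methylome(cfg, genome)
dmrs = dmr.call_dmrs(matrix, sheet, seed=4)

annotated = annotate.annotate_dmr_location(dmrs, genome)
print("location breakdown of hyper-DMRs:")
hyper = annotated[annotated["dmr_class"] == "hyper"]
print(hyper[["chrom", "start", "end", "location", "gene_id"]]
      .to_string(index=False))

assoc = annotate.associate_dmr_gene(dmrs, genome)
print(f"\n{len(assoc)} DMR-gene regulatory links "
      f"(expected hosts: {', '.join(hosts)}):")
print(assoc.to_string(index=False))

regions = annotate.build_region_set(genome)
summary = annotate.region_methylation_summary(matrix, regions, sheet)
print("\nmean beta by region (promoters dip ~20 points below bodies):")
print(summary.to_string(index=False))
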