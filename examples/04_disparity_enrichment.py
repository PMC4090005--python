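"""The acetylation/methylation disparity statistic and class enrichment.

Per gene, the statistic is log2(H3K9ac / H3K4me3) computed from the peak
region signals.  Ranked genes are split into three equal sectors (high
acetylation / intermediate / high methylation) and each annotated gene
class is tested for enrichment with a one-sided hypergeometric test.
The generator plants +1 log2 of acetylation at OPN genes and +1 log2 of
methylation at DPN genes, which the analysis should recover.
"""

import pandas as pd

from chromdiverge import disparity as disp
from chromdiverge import metagene as mg
from chromdiverge import simulate as sim
from chromdiverge import tracks as trk

config = sim.SimulationConfig(n_genes=1000, reads_per_sample=400_000,
                              disparity_effect=1.0, seed=11)
genomes = sim.generate_genomes(config)
landscape, _ = sim.plant_landscapes(genomes, config)
genes = genomes.annotation_a
lengths = pd.Series({g.gene_id: g.length for g in genes})


def merged(mark, stage):
    reads = sim.simulate_chip_reads(landscape, mark, genomes.nucleosomes_a,
                                    genomes.chrom_sizes, config, stage=stage)
    fwd, rev = trk.build_strand_profiles(reads, genomes.chrom_sizes)
    return trk.merge_strands(fwd, rev, config.fragment_length - 1)


ac = mg.region_means(merged("H3K9ac", 3), genes, "peak_ac")
me = mg.region_means(merged("H3K4me3", 4), genes, "peak_me")

records = disp.disparity_ratios(ac, me, lengths, min_gene_length=700)
records = disp.assign_sectors(records, sector_size=250)
print(records["sector"].value_counts().to_string())
print(f"\nconcordant genes (|ratio - median| <= 0.5): "
      f"{disp.concordance_fraction(records):.1f}%")

class_sets = {n: set(s["gene_id"])
              for n, s in genomes.classes.groupby("class_name")}
table = disp.sector_enrichment_table(records, class_sets)
view = table[table["class_name"].isin(["OPN", "DPN"])]
print("\nOPN/DPN enrichment by sector (fe = % over null expectation):")
print(view[["class_name", "sector", "k", "fe", "p_enrich"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nOPN genes concentrate in the high-acetylation sector and DPN genes")
print("in the high-methylation sector, with tiny hypergeometric p-values --")
print("the planted class-biased disparity, recovered through the read level.")
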