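"""Estimate the ChIP fragment length from strand cross-correlation.

Single-end reads are scored at their first sequenced base on separate
forward/reverse profiles; sliding the reverse profile base by base, the
shift maximizing the Spearman correlation between strands estimates the
average fragment length (the classic strand-shift method).
"""

from chromdiverge import simulate as sim
from chromdiverge import tracks as trk

config = sim.SimulationConfig(n_genes=200, n_chroms=2,
                              reads_per_sample=100_000,
                              fragment_length=125, seed=7)
genomes = sim.generate_genomes(config)
landscape, _ = sim.plant_landscapes(genomes, config)
reads = sim.simulate_chip_reads(landscape, "H3K9ac", genomes.nucleosomes_a,
                                genomes.chrom_sizes, config)

fwd, rev = trk.build_strand_profiles(reads, genomes.chrom_sizes)
offset, corr = trk.estimate_fragment_length(fwd, rev, max_shift=250)

print(f"planted fragment length : {config.fragment_length} bp")
print(f"estimated offset        : {offset} bp")
print(f"strand rank correlation : {corr:.3f}")
print("\nThe estimate lands within a few bases of the planted length; the")
print("correlation at the optimum is the strand agreement after alignment")
print("(higher sequencing depth pushes it toward 1).")

track = trk.merge_strands(fwd, rev, offset)
print(f"\nmerged track total = {track.total():.0f} reads "
      f"({track.meta['edge_lost']:.0f} lost at chromosome edges)")
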