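"""Metagene profiles: H3K9ac peaks at the TSS, H3K4me3 over the proximal ORF.

Builds coverage tracks for the three marks, bins them in 20-bp windows
around the TSS in transcription orientation, and prints where each
modification's average profile peaks -- before and after normalizing for
nucleosome occupancy by subtracting the smoothed log2 H3 track.
"""

from chromdiverge import metagene as mg
from chromdiverge import simulate as sim
from chromdiverge import tracks as trk

config = sim.SimulationConfig(n_genes=500, n_chroms=2,
                              reads_per_sample=400_000, seed=11)
genomes = sim.generate_genomes(config)
landscape, _ = sim.plant_landscapes(genomes, config)

merged = {}
for stage, mark in enumerate(sim.MARKS, start=3):
    reads = sim.simulate_chip_reads(landscape, mark, genomes.nucleosomes_a,
                                    genomes.chrom_sizes, config, stage=stage)
    fwd, rev = trk.build_strand_profiles(reads, genomes.chrom_sizes)
    merged[mark] = trk.merge_strands(fwd, rev, config.fragment_length - 1)
merged = dict(zip(merged, trk.normalize_to_lowest_total(list(merged.values()))))

h3_log = trk.smooth_track(trk.log2_track(merged["H3"]))  # 140-base window
genes = genomes.annotation_a

print("average TSS-profile argmax (bp relative to TSS):")
for mark in ("H3K9ac", "H3K4me3"):
    mat = mg.gene_profile_matrix(merged[mark], genes, mg.TSS_WINDOW)
    raw_peak = int(mg.average_profile(mat).idxmax())
    norm = trk.h3_normalize(trk.log2_track(merged[mark]), h3_log)
    mat_n = mg.gene_profile_matrix(norm, genes, mg.TSS_WINDOW)
    norm_peak = int(mg.average_profile(mat_n).idxmax())
    print(f"  {mark:8s}  raw: {raw_peak:+5d}   H3-normalized: {norm_peak:+5d}")

print("\nH3K9ac peaks inside its 0..+140 'peak' region (the +1 nucleosome);")
print("H3K4me3 peaks inside +100..+580 (nucleosomes +2/+3); both survive")
print("H3 normalization, so the preference is not a nucleosome-density artifact.")
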