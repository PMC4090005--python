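"""Generator invariants: determinism, planted structure, coupling behavior."""

import numpy as np
import pandas as pd
import pytest

from chromdiverge import expression as expr
from chromdiverge import simulate as sim


def test_generation_is_deterministic():
    cfg = sim.SimulationConfig(n_genes=10, n_chroms=1, seed=7)
    g1 = sim.generate_genomes(cfg)
    g2 = sim.generate_genomes(cfg)
    assert g1.annotation_a == g2.annotation_a
    assert g1.nucleosomes_b == g2.nucleosomes_b
    pd.testing.assert_frame_equal(g1.orthologs, g2.orthologs)
    pd.testing.assert_frame_equal(g1.classes, g2.classes)


def test_ortholog_fraction_binomial():
    cfg = sim.SimulationConfig(n_genes=1000, seed=5, ortholog_fraction=0.9)
    g = sim.generate_genomes(cfg)
    n = len(g.orthologs)
    # 4 sigma around np = 900, sigma = sqrt(1000 * 0.9 * 0.1) ~ 9.5
    assert 862 <= n <= 938


def test_opn_dpn_disjoint_with_expected_sizes():
    fr = sim._default_class_fractions() | {"OPN": 0.3, "DPN": 0.3}
    cfg = sim.SimulationConfig(n_genes=1000, seed=2, class_fractions=fr)
    g = sim.generate_genomes(cfg)
    sets = {k: set(v["gene_id"]) for k, v in g.classes.groupby("class_name")}
    assert len(sets["OPN"]) == 300 and len(sets["DPN"]) == 300
    assert not sets["OPN"] & sets["DPN"]


def test_genes_do_not_fit_raises():
    cfg = sim.SimulationConfig(n_genes=100, n_chroms=1, chrom_len=10_000)
    with pytest.raises(ValueError, match="fit"):
        sim.generate_genomes(cfg)


def test_no_disparity_and_no_mark_noise_gives_identical_amplitudes():
    cfg = sim.SimulationConfig(n_genes=200, disparity_effect=0.0, mark_log_sd=0.0,
                               seed=4)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    ac = np.log2(land_a.intensity["H3K9ac"][1])
    me = np.log2(land_a.intensity["H3K4me3"][2])
    # same per-gene amplitude, different constant shape factor
    r = np.corrcoef(ac, me)[0, 1]
    assert r > 0.999999


def test_full_methylation_coupling_copies_expression_divergence():
    cfg = sim.SimulationConfig(n_genes=500, k4_expr_coupling=1.0,
                               divergence_sd_expr=0.5, seed=9)
    g = sim.generate_genomes(cfg)
    land_a, land_b = sim.plant_landscapes(g, cfg)
    d_expr = land_b.expression.to_numpy() - land_a.expression.to_numpy()
    d_me = np.log2(land_b.intensity["H3K4me3"][2].to_numpy()) - np.log2(
        land_a.intensity["H3K4me3"][2].to_numpy()
    )
    np.testing.assert_allclose(d_me, d_expr, atol=1e-9)


def test_zero_acetylation_coupling_decorrelates():
    cfg = sim.SimulationConfig(n_genes=1000, k9_expr_coupling=0.0, seed=13)
    g = sim.generate_genomes(cfg)
    land_a, land_b = sim.plant_landscapes(g, cfg)
    d_expr = land_b.expression.to_numpy() - land_a.expression.to_numpy()
    d_ac = np.log2(land_b.intensity["H3K9ac"][1].to_numpy()) - np.log2(
        land_a.intensity["H3K9ac"][1].to_numpy()
    )
    assert abs(np.corrcoef(d_ac, d_expr)[0, 1]) < 0.1


def test_chip_fragments_respect_intensity_support():
    cfg = sim.SimulationConfig(n_genes=4, n_chroms=1, reads_per_sample=2000,
                               fragment_length=150, seed=1)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    # concentrate all emission on the +1 nucleosome of the first gene
    gid = g.annotation_a[0].gene_id
    for mark in sim.MARKS:
        land_a.intensity[mark].loc[:, :] = 0.0
    land_a.intensity["H3K9ac"].loc[gid, 1] = 5.0
    reads = sim.simulate_chip_reads(land_a, "H3K9ac", g.nucleosomes_a,
                                    g.chrom_sizes, cfg)
    nuc = next(r for r in g.nucleosomes_a if r.gene_id == gid and r.index == 1)
    fl = cfg.fragment_length
    frag_start = np.where(reads["strand"] == "+", reads["pos"],
                          reads["pos"] - fl + 1)
    mid = frag_start + fl // 2
    assert (mid >= nuc.start).all() and (mid < nuc.end).all()


def test_zero_total_intensity_raises():
    cfg = sim.SimulationConfig(n_genes=4, n_chroms=1, seed=1)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    land_a.intensity["H3"].loc[:, :] = 0.0
    with pytest.raises(ValueError, match="zero total"):
        sim.simulate_chip_reads(land_a, "H3", g.nucleosomes_a, g.chrom_sizes, cfg)


def test_read_yield_scales_with_requested_depth():
    cfg1 = sim.SimulationConfig(n_genes=50, n_chroms=1, reads_per_sample=20_000,
                                seed=8)
    cfg2 = sim.SimulationConfig(n_genes=50, n_chroms=1, reads_per_sample=40_000,
                                seed=8)
    g = sim.generate_genomes(cfg1)
    land_a, _ = sim.plant_landscapes(g, cfg1)
    r1 = sim.simulate_chip_reads(land_a, "H3K9ac", g.nucleosomes_a, g.chrom_sizes, cfg1)
    r2 = sim.simulate_chip_reads(land_a, "H3K9ac", g.nucleosomes_a, g.chrom_sizes, cfg2)
    assert abs(len(r2) / len(r1) - 2.0) < 0.1


def test_expression_counts_zero_for_silent_gene():
    cfg = sim.SimulationConfig(n_genes=20, n_chroms=1, seed=6)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    gid = g.annotation_a[0].gene_id
    land_a.expression.loc[gid] = -np.inf  # linear intensity 0
    counts = sim.simulate_expression_counts(land_a, g.annotation_a, cfg)
    assert (counts.loc[gid] == 0).all()


def test_expression_recovery_correlates_with_truth():
    cfg = sim.SimulationConfig(n_genes=1000, rna_depth=1_000_000, seed=12)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    counts = sim.simulate_expression_counts(land_a, g.annotation_a, cfg)
    lengths = pd.Series({x.gene_id: x.length for x in g.annotation_a})
    est = expr.quantify_expression(counts, lengths)
    r = est.corr(land_a.expression)
    assert r > 0.95


def test_compendium_recovers_planted_responsive_genes():
    cfg = sim.SimulationConfig(n_genes=1000, n_conditions=200, seed=21)
    g = sim.generate_genomes(cfg)
    land_a, _ = sim.plant_landscapes(g, cfg)
    comp = sim.generate_compendium(land_a, g.classes, cfg)
    planted = set(g.classes.loc[g.classes["class_name"] == "responsive", "gene_id"])
    table = expr.responsiveness_classes(comp, n=len(planted))
    called = set(table.loc[table["class_name"] == "responsive", "gene_id"])
    assert len(called & planted) / len(planted) >= 0.95
    # determinism
    comp2 = sim.generate_compendium(land_a, g.classes, cfg)
    pd.testing.assert_frame_equal(comp, comp2)
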