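"""End-to-end orchestration: simulate/ingest -> tracks -> metagene ->
expression -> disparity -> divergence, with TSV outputs, a summary JSON and
a markdown report.

Every analysis constant (20 bp bins, 140-base H3 smoothing, 0.4 log2
change threshold, 700 bp minimal gene length, sector and extreme-set
sizes, region coordinates) is a named config key, so the standard analysis
is simply the default run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chromdiverge import disparity as disp
from chromdiverge import divergence as dive
from chromdiverge import expression as expr
from chromdiverge import io as cio
from chromdiverge import metagene as mg
from chromdiverge import simulate as sim
from chromdiverge import tracks as trk

logger = logging.getLogger("chromdiverge")

MOD_MARKS = ("H3K9ac", "H3K4me3")


@dataclass
class PipelineConfig:
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    out_dir: str = "chromdiverge_out"
    pseudocount: float = 1.0
    fragment_length: str | int = "auto"  # "auto": estimate per sample
    max_shift: int = 300
    smooth_window: int = trk.H3_SMOOTH_WINDOW
    min_gene_length: int = disp.MIN_GENE_LENGTH
    sector_size: int = disp.SECTOR_SIZE
    change_threshold: float = dive.CHANGE_THRESHOLD
    concordance_cutoff: float = 0.5
    n_extreme: int = 1000
    n_per_side: int = 800
    lowess_span: float = 0.3
    responsiveness_n: int = 1000

    def validate(self) -> None:
        self.simulation.validate()
        for name in ("sector_size", "min_gene_length", "n_extreme", "n_per_side",
                     "responsiveness_n", "max_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def demo_config(seed: int = 0, out_dir: str = "chromdiverge_out") -> PipelineConfig:
    """A small configuration that exercises every stage in well under a minute."""
    simcfg = sim.SimulationConfig(
        n_genes=400, n_chroms=2, reads_per_sample=150_000, rna_depth=400_000,
        n_conditions=60, seed=seed,
    )
    return PipelineConfig(
        simulation=simcfg, out_dir=out_dir, sector_size=80, n_extreme=60,
        n_per_side=50, responsiveness_n=60, max_shift=250,
    )


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    d = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    simcfg = sim.SimulationConfig(**d.pop("simulation", {}))
    return PipelineConfig(simulation=simcfg, **d)


# ---------------------------------------------------------------------------


def build_mark_tracks(
    dataset: sim.SimulatedDataset, config: PipelineConfig
) -> tuple[dict[tuple[str, str], trk.CoverageTrack], dict]:
    """Stranded reads -> merged, depth-normalized linear tracks per sample.

    Returns tracks keyed by (species, mark) and a stats dict with the
    estimated fragment length and strand correlation per sample.
    """
    chrom_sizes = dataset.genomes.chrom_sizes
    merged: dict[tuple[str, str], trk.CoverageTrack] = {}
    stats: dict = {}
    for (species, mark), reads in dataset.chip_reads.items():
        fwd, rev = trk.build_strand_profiles(reads, chrom_sizes)
        if config.fragment_length == "auto":
            offset, corr = trk.estimate_fragment_length(fwd, rev, config.max_shift)
        else:
            offset, corr = int(config.fragment_length), np.nan
        track = trk.merge_strands(fwd, rev, offset, name=f"{mark}_{species}")
        merged[(species, mark)] = track
        stats[f"{species}/{mark}"] = {
            "fragment_length": int(offset),
            "strand_correlation": None if np.isnan(corr) else round(float(corr), 4),
            "reads": int(fwd.total_reads + rev.total_reads),
        }
        logger.info("tracks %s/%s: offset=%s corr=%s", species, mark, offset, corr)
    normalized = trk.normalize_to_lowest_total(list(merged.values()))
    merged = dict(zip(merged.keys(), normalized))
    return merged, stats


def h3_normalized_tracks(
    merged: dict[tuple[str, str], trk.CoverageTrack], config: PipelineConfig
) -> dict[tuple[str, str], trk.CoverageTrack]:
    """log2 modification tracks minus the smoothed log2 H3 track."""
    out = {}
    for species in ("A", "B"):
        h3 = trk.smooth_track(
            trk.log2_track(merged[(species, "H3")], config.pseudocount),
            config.smooth_window,
        )
        for mark in MOD_MARKS:
            mod = trk.log2_track(merged[(species, mark)], config.pseudocount)
            out[(species, mark)] = trk.h3_normalize(mod, h3)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; writes TSVs, summary.json and report.md.

    Returns the summary dict.  Deterministic given the config (and its
    simulation seed): reruns produce byte-identical outputs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {"seed": config.simulation.seed,
                                "n_genes": config.simulation.n_genes}}

    logger.info("stage simulate: n_genes=%d", config.simulation.n_genes)
    dataset = sim.simulate_dataset(config.simulation)
    genomes = dataset.genomes
    genes_a, genes_b = genomes.annotation_a, genomes.annotation_b
    lengths_a = pd.Series({g.gene_id: g.length for g in genes_a})

    cio.write_genes(genes_a, out_dir / "genes_A.tsv")
    cio.write_genes(genes_b, out_dir / "genes_B.tsv")
    cio.write_table(genomes.orthologs, out_dir / "orthologs.tsv", "orthologs")
    cio.write_table(genomes.classes, out_dir / "classes.tsv", "classes")

    logger.info("stage tracks: %d samples", len(dataset.chip_reads))
    merged, track_stats = build_mark_tracks(dataset, config)
    summary["tracks"] = track_stats
    h3norm = h3_normalized_tracks(merged, config)

    # --- metagene (species A), expression coupling ---
    logger.info("stage metagene")
    mats_tss = {
        mark: mg.gene_profile_matrix(merged[("A", mark)], genes_a, mg.TSS_WINDOW,
                                     config.pseudocount)
        for mark in MOD_MARKS
    }
    mats_tts = {
        mark: mg.gene_profile_matrix(merged[("A", mark)], genes_a, mg.TTS_WINDOW,
                                     config.pseudocount)
        for mark in MOD_MARKS
    }
    mats_tss_h3 = {
        mark: mg.gene_profile_matrix(h3norm[("A", mark)], genes_a, mg.TSS_WINDOW)
        for mark in MOD_MARKS
    }
    avg_profiles = pd.DataFrame(
        {
            f"{mark}_TSS": mg.average_profile(mats_tss[mark]) for mark in MOD_MARKS
        }
    )
    avg_profiles.index.name = "bin_start"
    avg_profiles.to_csv(out_dir / "metagene_tss.tsv", sep="\t")
    summary["metagene"] = {
        f"{mark}_tss_argmax_bp": int(mg.average_profile(mats_tss[mark]).idxmax())
        for mark in MOD_MARKS
    }
    summary["metagene"].update(
        {
            f"{mark}_tss_argmax_bp_h3norm": int(
                mg.average_profile(mats_tss_h3[mark]).idxmax()
            )
            for mark in MOD_MARKS
        }
    )

    logger.info("stage expression")
    expr_a = expr.quantify_expression(dataset.rna_counts["A"], lengths_a)
    lengths_b = pd.Series({g.gene_id: g.length for g in genes_b})
    expr_b = expr.quantify_expression(dataset.rna_counts["B"], lengths_b)
    expr_a.to_csv(out_dir / "expression_A.tsv", sep="\t")
    expr_b.to_csv(out_dir / "expression_B.tsv", sep="\t")

    resp = expr.responsiveness_classes(dataset.compendium, config.responsiveness_n)
    class_table = pd.concat([genomes.classes, resp], ignore_index=True)
    class_sets = cio.classes_to_sets(class_table.drop_duplicates())

    # nucleosome-level expression correlation (species A)
    nuc_levels = {
        mark: mg.nucleosome_level_matrix(
            mg.nucleosome_levels(merged[("A", mark)], genomes.nucleosomes_a,
                                 config.pseudocount)
        )
        for mark in MOD_MARKS
    }
    nuc_corr = pd.DataFrame(
        {mark: mg.positional_correlation(nuc_levels[mark], expr_a)
         for mark in MOD_MARKS}
    )
    nuc_corr.index.name = "nucleosome"
    nuc_corr.to_csv(out_dir / "nucleosome_expression_correlation.tsv", sep="\t")
    summary["positional_correlation"] = {
        f"{mark}_peak_nucleosome": int(nuc_corr[mark].idxmax()) for mark in MOD_MARKS
    }

    # --- disparity (species A) ---
    logger.info("stage disparity")
    region_ac_a = mg.region_means(merged[("A", "H3K9ac")], genes_a, "peak_ac",
                                  config.pseudocount)
    region_me_a = mg.region_means(merged[("A", "H3K4me3")], genes_a, "peak_me",
                                  config.pseudocount)
    records = disp.disparity_ratios(region_ac_a, region_me_a, lengths_a,
                                    config.min_gene_length)
    records = disp.assign_sectors(records, config.sector_size)
    records.to_csv(out_dir / "disparity.tsv", sep="\t")
    enrich = disp.sector_enrichment_table(records, class_sets)
    enrich.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    summary["disparity"] = {
        "concordant_pct": round(
            disp.concordance_fraction(records, config.concordance_cutoff), 2
        ),
        "n_ranked": int(records["ratio"].notna().sum()),
    }
    for cls, sector in (("OPN", "high_ac"), ("DPN", "high_me")):
        row = enrich[(enrich["class_name"] == cls) & (enrich["sector"] == sector)]
        if len(row):
            summary["disparity"][f"{cls}_{sector}_p"] = float(row["p_enrich"].iloc[0])
            summary["disparity"][f"{cls}_{sector}_fe_pct"] = round(
                float(row["fe"].iloc[0]), 2
            )

    # --- divergence ---
    logger.info("stage divergence")
    orth = genomes.orthologs
    region_ac_b = mg.region_means(merged[("B", "H3K9ac")], genes_b, "peak_ac",
                                  config.pseudocount)
    region_me_b = mg.region_means(merged[("B", "H3K4me3")], genes_b, "peak_me",
                                  config.pseudocount)
    paired_ac = dive.paired_region_signals(region_ac_a, region_ac_b, orth, "peak_ac")
    paired_me = dive.paired_region_signals(region_me_a, region_me_b, orth, "peak_me")

    d_expr_all = pd.Series(
        expr_a.reindex(orth["gene_id_a"]).to_numpy()
        - expr_b.reindex(orth["gene_id_b"]).to_numpy(),
        index=pd.Index(orth["gene_id_a"], name="gene_id"),
    )
    common = paired_ac.index.intersection(paired_me.index)
    d_ac = paired_ac.loc[common, "d"]
    d_me = paired_me.loc[common, "d"]
    d_expr = d_expr_all.loc[common]

    div_table = pd.DataFrame({"d_ac": d_ac, "d_me": d_me, "d_expr": d_expr})
    t = config.change_threshold
    for col in ("d_ac", "d_me", "d_expr"):
        div_table[f"significant_{col[2:]}"] = div_table[col].abs() > t
    pair_labels, pair_props = dive.classify_change_pair(d_ac, d_me, t)
    div_table["ac_me_class"] = pair_labels
    triple_labels, triple_props = dive.triple_classification(d_ac, d_me, d_expr, t)
    div_table["triple_class"] = triple_labels
    div_table.to_csv(out_dir / "divergence.tsv", sep="\t")

    exceed = pd.DataFrame(
        {
            "peak_ac": dive.divergence_exceedance(d_ac),
            "peak_me": dive.divergence_exceedance(d_me),
            "expression": dive.divergence_exceedance(d_expr),
        }
    )
    exceed.index.name = "threshold"
    exceed.to_csv(out_dir / "divergence_exceedance.tsv", sep="\t")

    grid = np.round(np.arange(t, 1.01, 0.1), 10)
    consistency = pd.DataFrame(
        {
            "H3K9ac": dive.consistency_vs_threshold(d_expr, d_ac, t, grid),
            "H3K4me3": dive.consistency_vs_threshold(d_expr, d_me, t, grid),
        }
    )
    consistency.index.name = "threshold"
    consistency.to_csv(out_dir / "consistency_vs_threshold.tsv", sep="\t")

    n_extreme = min(config.n_extreme, len(common) // 2)
    fold = pd.DataFrame(
        {
            "H3K9ac": dive.divergent_enrichment_curve(d_expr, d_ac, n_extreme),
            "H3K4me3": dive.divergent_enrichment_curve(d_expr, d_me, n_extreme),
        }
    )
    fold.index.name = "threshold"
    fold.to_csv(out_dir / "divergent_enrichment.tsv", sep="\t")

    n_side = min(config.n_per_side, len(common) // 2)
    low_sets = {}
    for mark, paired in (("H3K9ac", paired_ac), ("H3K4me3", paired_me)):
        a_high, b_high = dive.lowess_divergent_genes(
            paired.loc[common, "value_a"], paired.loc[common, "value_b"],
            n_side, config.lowess_span,
        )
        low_sets[mark] = {"a_high": a_high, "b_high": b_high}

    summary["divergence"] = {
        "n_orthologs": int(len(common)),
        "interspecies_r_peak_ac": round(
            float(paired_ac["value_a"].corr(paired_ac["value_b"])), 4
        ),
        "interspecies_r_peak_me": round(
            float(paired_me["value_a"].corr(paired_me["value_b"])), 4
        ),
        "pair_class_pct": {k: round(100 * v, 2) for k, v in pair_props.items()},
        "triple_class_pct": {k: round(100 * v, 2) for k, v in triple_props.items()},
        "r_ac_expr": round(float(d_ac.corr(d_expr)), 4),
        "r_me_expr": round(float(d_me.corr(d_expr)), 4),
        "gated_r_ac_expr": round(
            dive.threshold_gated_correlation(d_expr, d_ac, t), 4
        ),
        "gated_r_me_expr": round(
            dive.threshold_gated_correlation(d_expr, d_me, t), 4
        ),
    }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    make_report(summary, out_dir / "report.md")
    logger.info("pipeline complete: %s", out_dir)
    return summary


REPORT_SECTIONS = (
    ("tracks", "Fragment-length estimation and library normalization"),
    ("metagene", "Average modification profiles around the TSS"),
    ("positional_correlation", "Expression correlation at individual nucleosomes"),
    ("disparity", "Acetylation/methylation disparity sectors and class enrichment"),
    ("divergence", "Interspecies divergence of modifications and expression"),
)


def make_report(summary: dict, path: str | Path) -> str:
    """Render the summary dict as a short markdown report."""
    lines = ["# chromdiverge run report", ""]
    for key, title in REPORT_SECTIONS:
        lines.append(f"## {title}")
        if key not in summary:
            lines.append("*absent: stage did not produce output*")
        else:
            lines.append("```json")
            lines.append(json.dumps(summary[key], indent=2, sort_keys=True))
            lines.append("```")
        lines.append("")
    text = "\n".join(lines)
    with open(path, "w") as fh:
        fh.write(text)
    return text
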