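"""Gene-anchored profiles: binned matrices, metagene traces, region means.

Windows and regions are expressed in transcription-relative coordinates:
offset r of a gene maps to genomic position ``anchor + r`` on the plus
strand and ``anchor - r`` on the minus strand, so bin 0 of a TSS window is
always upstream-most regardless of strand.

The named regions are the standard ones for this analysis: the promoter
(-320..-160 of the TSS), the per-mark peak regions (0..+140 for H3K9ac,
+100..+580 for H3K4me3), the gene end (-260..+60 of the TTS), the broad
proximal ORF (-60..+580, essentially nucleosomes +1 to +4), and the
H3-normalization variant of the acetylation peak (-60..+140).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromdiverge.io import CoverageTrack, GeneModel, NucleosomeRecord


@dataclass(frozen=True)
class WindowDef:
    anchor: str  # "TSS" or "TTS"
    start: int
    end: int
    bin: int = 20

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if (self.end - self.start) % self.bin:
            raise ValueError("window width must be divisible by bin size")

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.bin

    def bin_starts(self) -> np.ndarray:
        return self.start + self.bin * np.arange(self.n_bins)


@dataclass(frozen=True)
class RegionDef:
    name: str
    anchor: str
    start: int
    end: int


#: Default profile windows around the TSS and TTS.
TSS_WINDOW = WindowDef("TSS", -500, 900, 20)
TTS_WINDOW = WindowDef("TTS", -400, 200, 20)

#: Named region constants.
REGIONS: dict[str, RegionDef] = {
    "prom": RegionDef("prom", "TSS", -320, -160),
    "peak_ac": RegionDef("peak_ac", "TSS", 0, 140),
    "peak_me": RegionDef("peak_me", "TSS", 100, 580),
    "end": RegionDef("end", "TTS", -260, 60),
    "orf_broad": RegionDef("orf_broad", "TSS", -60, 580),
    "peak_ac_h3norm": RegionDef("peak_ac_h3norm", "TSS", -60, 140),
}


@dataclass
class GeneProfileMatrix:
    """genes x bins matrix of log2 signal; NaN marks missing bins."""

    values: pd.DataFrame
    window: WindowDef
    mode: str  # "log_of_mean" (from linear track) or "mean_of_log" (log2 track)


def _anchor_pos(gene: GeneModel, anchor: str) -> int:
    return gene.tss if anchor == "TSS" else gene.tts


def _positions(gene: GeneModel, anchor: str, r0: int, r1: int) -> np.ndarray:
    """Genomic positions of transcription-relative offsets [r0, r1)."""
    a = _anchor_pos(gene, anchor)
    rel = np.arange(r0, r1)
    return a + rel if gene.strand == "+" else a - rel


def gene_profile_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    window: WindowDef,
    pseudocount: float = 1.0,
) -> GeneProfileMatrix:
    """Binned per-gene profiles around the window anchor.

    Given a linear track each bin is log2(mean linear signal + pseudocount)
    over its 20 bp; given a log2 track it is the mean of the per-base log2
    values (mode recorded).  Bins that reach past a chromosome edge are
    masked (NaN), not truncated.
    """
    is_linear = track.scale == "linear"
    nb = window.n_bins
    rows = np.full((len(genes), nb), np.nan)
    for i, gene in enumerate(genes):
        chrom = track.data.get(gene.chrom)
        if chrom is None:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
        pos = _positions(gene, window.anchor, window.start, window.end)
        ok = (pos >= 0) & (pos < len(chrom))
        vals = np.full(pos.shape, np.nan)
        vals[ok] = chrom[pos[ok]]
        binned = vals.reshape(nb, window.bin)
        good = ~np.isnan(binned).any(axis=1)
        means = binned.mean(axis=1)  # NaN propagates for masked bins
        if is_linear:
            rows[i, good] = np.log2(means[good] + pseudocount)
        else:
            rows[i, good] = means[good]
    values = pd.DataFrame(
        rows,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=window.bin_starts(),
    )
    mode = "log_of_mean" if is_linear else "mean_of_log"
    return GeneProfileMatrix(values, window, mode)


def average_profile(
    matrix: GeneProfileMatrix, gene_subset: list[str] | None = None
) -> pd.Series:
    """Per-bin mean over unmasked cells, optionally over a gene subset."""
    values = matrix.values
    if gene_subset is not None:
        values = values.loc[values.index.intersection(list(gene_subset))]
    if values.empty:
        raise ValueError("empty gene subset")
    return values.mean(axis=0, skipna=True)


def nucleosome_levels(
    track: CoverageTrack,
    nucleosomes: list[NucleosomeRecord],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-(gene, nucleosome index) log2 mean signal.

    Linear tracks give log2(mean + pseudocount); log2 tracks give the mean
    of log2 values.  Returns a tidy frame gene_id / index / value.
    """
    is_linear = track.scale == "linear"
    recs = []
    for rec in nucleosomes:
        chrom = track.data.get(rec.chrom)
        if chrom is None or rec.start < 0 or rec.end > len(chrom):
            raise ValueError(
                f"nucleosome {rec.gene_id}/{rec.index} outside chromosome bounds"
            )
        m = float(chrom[rec.start: rec.end].mean())
        value = np.log2(m + pseudocount) if is_linear else m
        recs.append((rec.gene_id, rec.index, value))
    return pd.DataFrame(recs, columns=["gene_id", "index", "value"])


def nucleosome_level_matrix(levels: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy nucleosome levels to a genes x index matrix."""
    return levels.pivot(index="gene_id", columns="index", values="value")


def region_means(
    track: CoverageTrack,
    genes: list[GeneModel],
    region: RegionDef | str,
    pseudocount: float = 1.0,
    bin: int = 20,
) -> pd.DataFrame:
    """Per-gene log2 mean signal over a named region.

    The region is tiled with 20 bp bins exactly as in the profile matrices
    (every named region's width is a multiple of 20), each bin scored as
    log2(mean linear + pseudocount) (or the mean of log2 values for a log2
    track), and the per-gene value is the mean over the region's bins --
    so a region mean equals the mean of the corresponding profile-matrix
    bins.  Genes whose region reaches past a chromosome edge are flagged
    ``valid=False`` (value NaN) and are excluded downstream, matching the
    exclusion of genes lacking data for a modification.
    """
    if isinstance(region, str):
        region = REGIONS[region]
    if (region.end - region.start) % bin:
        raise ValueError("region width must be divisible by the bin size")
    is_linear = track.scale == "linear"
    nb = (region.end - region.start) // bin
    out = []
    for gene in genes:
        chrom = track.data.get(gene.chrom)
        if chrom is None:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
        pos = _positions(gene, region.anchor, region.start, region.end)
        if pos.min() < 0 or pos.max() >= len(chrom):
            out.append((gene.gene_id, np.nan, False))
            continue
        bin_means = chrom[pos].reshape(nb, bin).mean(axis=1)
        if is_linear:
            value = float(np.log2(bin_means + pseudocount).mean())
        else:
            value = float(bin_means.mean())
        out.append((gene.gene_id, value, True))
    df = pd.DataFrame(out, columns=["gene_id", "value", "valid"])
    df["region"] = region.name
    return df.set_index("gene_id")


def positional_correlation(
    matrix: pd.DataFrame | GeneProfileMatrix,
    y: pd.Series,
    method: str = "pearson",
    min_genes: int = 3,
) -> pd.Series:
    """Correlation of each column of a genes x positions matrix with y.

    Positions with fewer than ``min_genes`` jointly valid genes are masked
    (NaN).  ``method`` is ``pearson`` (default) or ``spearman``.
    """
    values = matrix.values if isinstance(matrix, GeneProfileMatrix) else matrix
    y = y.reindex(values.index)
    out = {}
    for col in values.columns:
        x = values[col]
        ok = x.notna() & y.notna()
        if ok.sum() < min_genes:
            out[col] = np.nan
        else:
            out[col] = x[ok].corr(y[ok], method=method)
    return pd.Series(out)
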