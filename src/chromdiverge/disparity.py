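"""The per-gene acetylation/methylation disparity statistic.

The statistic is the log2 ratio of H3K9ac to H3K4me3 region signals at a
gene (computed as the difference of log2 region means).  Genes above a
minimal length are ranked by this ratio and split into three sectors of
equal size -- highest ranked (H3K9ac > H3K4me3), intermediately ranked,
and lowest ranked (H3K4me3 > H3K9ac) -- which are then tested for
enrichment or depletion of annotated gene classes with a one-sided
hypergeometric test, reported alongside the percent fold enrichment over
the expected abundance under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default minimal gene length (bp) for the disparity ranking.
MIN_GENE_LENGTH = 700
#: Default sector size (genes per sector).
SECTOR_SIZE = 1200


def disparity_ratios(
    ac: pd.DataFrame,
    me: pd.DataFrame,
    gene_lengths: pd.Series,
    min_gene_length: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Per-gene log2(H3K9ac/H3K4me3) from region-mean frames.

    ``ac`` and ``me`` are region_means outputs (index gene_id, columns
    value/valid).  Genes shorter than ``min_gene_length`` or with either
    signal invalid get sector ``unassigned`` and an undefined (NaN) ratio.
    """
    idx = ac.index.intersection(me.index)
    df = pd.DataFrame(index=idx)
    df["ac"] = ac.loc[idx, "value"]
    df["me"] = me.loc[idx, "value"]
    ok = (
        ac.loc[idx, "valid"].astype(bool)
        & me.loc[idx, "valid"].astype(bool)
        & (gene_lengths.reindex(idx) >= min_gene_length)
    )
    df["ratio"] = np.where(ok, df["ac"] - df["me"], np.nan)
    df["sector"] = "unassigned"
    return df


def assign_sectors(records: pd.DataFrame, sector_size: int = SECTOR_SIZE) -> pd.DataFrame:
    """Split ratio-ranked genes into high_ac / mid / high_me sectors.

    Genes with a defined ratio are sorted by ratio descending (ties by gene
    id): the top ``sector_size`` become ``high_ac``, the bottom
    ``sector_size`` become ``high_me``, and the ``sector_size`` genes
    centered on the median rank become ``mid``.  Everything else stays
    ``unassigned``.
    """
    out = records.copy()
    defined = out.loc[out["ratio"].notna()]
    m = len(defined)
    if m < 3 * sector_size:
        raise ValueError(
            f"only {m} genes with defined ratios; need >= {3 * sector_size}"
        )
    ranked = defined.sort_index(kind="stable").sort_values(
        "ratio", ascending=False, kind="stable"
    )
    out.loc[ranked.index, "sector"] = "unassigned"
    out.loc[ranked.index[:sector_size], "sector"] = "high_ac"
    out.loc[ranked.index[-sector_size:], "sector"] = "high_me"
    mid_start = (m - sector_size) // 2
    out.loc[ranked.index[mid_start: mid_start + sector_size], "sector"] = "mid"
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    class_name: str
    sector: str
    universe_size: int
    class_size: int
    sector_size: int
    overlap: int
    p_enrich: float
    p_deplete: float
    fe: float  # percent fold enrichment over the null expectation
    direction: str

    @property
    def p_value(self) -> float:
        return self.p_enrich if self.direction == "enriched" else self.p_deplete


def hypergeom_enrichment(
    sector_genes: set[str],
    class_genes: set[str],
    universe: set[str],
    class_name: str = "",
    sector: str = "",
) -> EnrichmentResult:
    """One-sided hypergeometric enrichment/depletion of a class in a sector.

    With X ~ Hypergeometric(N, K, n) and observed overlap k:
    p_enrich = P[X >= k], p_deplete = P[X <= k]; the reported direction
    follows the sign of the percent fold enrichment
    fe = 100 * (k / (n*K/N) - 1).
    """
    sector_genes = set(sector_genes) & universe
    class_genes = set(class_genes) & universe
    if not sector_genes or not class_genes:
        raise ValueError("empty class or sector")
    N, K, n = len(universe), len(class_genes), len(sector_genes)
    k = len(sector_genes & class_genes)
    dist = stats.hypergeom(N, K, n)
    p_enrich = float(dist.sf(k - 1))
    p_deplete = float(dist.cdf(k))
    expected = n * K / N
    fe = 100.0 * (k / expected - 1.0)
    direction = "enriched" if fe >= 0 else "depleted"
    return EnrichmentResult(class_name, sector, N, K, n, k, p_enrich, p_deplete,
                            fe, direction)


def sector_enrichment_table(
    records: pd.DataFrame, class_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Enrichment of every class in every sector over the ranked universe.

    The universe is the set of genes with a defined disparity ratio.
    """
    universe = set(records.index[records["ratio"].notna()])
    rows = []
    for sector in ("high_ac", "mid", "high_me"):
        sector_genes = set(records.index[records["sector"] == sector])
        for name, members in class_sets.items():
            members_u = set(members) & universe
            if not members_u or not sector_genes:
                continue
            r = hypergeom_enrichment(sector_genes, members_u, universe, name, sector)
            rows.append(
                (r.class_name, r.sector, r.universe_size, r.class_size,
                 r.sector_size, r.overlap, r.p_enrich, r.p_deplete, r.fe,
                 r.direction)
            )
    return pd.DataFrame(
        rows,
        columns=["class_name", "sector", "N", "K", "n", "k", "p_enrich",
                 "p_deplete", "fe", "direction"],
    )


def concordance_fraction(records: pd.DataFrame, cutoff: float = 0.5) -> float:
    """Percent of defined-ratio genes within +/-cutoff of the median ratio."""
    ratios = records["ratio"].dropna()
    if ratios.empty:
        raise ValueError("no defined ratios")
    med = ratios.median()
    return float(100.0 * (np.abs(ratios - med) <= cutoff).mean())


def group_mean_disparity(
    ac: pd.DataFrame, me: pd.DataFrame, class_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-class mean H3K9ac and H3K4me3 region signals.

    Classes with no valid member genes are dropped.  The frame carries the
    across-class Pearson correlation in ``attrs["correlation"]``.
    """
    idx = ac.index.intersection(me.index)
    valid = (
        ac.loc[idx, "valid"].astype(bool) & me.loc[idx, "valid"].astype(bool)
    )
    valid_ids = set(idx[valid])
    rows = []
    for name, members in class_sets.items():
        ids = list(set(members) & valid_ids)
        if not ids:
            continue
        rows.append((name, float(ac.loc[ids, "value"].mean()),
                     float(me.loc[ids, "value"].mean()), len(ids)))
    df = pd.DataFrame(rows, columns=["class_name", "mean_ac", "mean_me", "n_genes"])
    if len(df) >= 3:
        df.attrs["correlation"] = float(df["mean_ac"].corr(df["mean_me"]))
    return df
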