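"""Interspecies comparison of orthologous genes.

Differences are oriented species A minus species B (Cer - Par style) in
log2 units.  A change is called significant when its absolute log2
difference exceeds a threshold, by default 0.4 (about 1.3-fold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

#: Default significance threshold on absolute log2 differences (~1.3-fold).
CHANGE_THRESHOLD = 0.4
#: Default grid for threshold-sweep curves (log2 units).
DEFAULT_GRID = np.round(np.arange(0.0, 2.01, 0.1), 10)

PAIR_CLASSES = ("none", "only_first", "only_second", "consistent", "opposite")
TRIPLE_CLASSES = ("none", "all_consistent", "ac_me_not_expr", "ac_expr_not_me",
                  "me_expr_not_ac", "other")


def paired_region_signals(
    signals_a: pd.DataFrame,
    signals_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    region: str = "",
) -> pd.DataFrame:
    """Juxtapose per-gene region signals of two species over the ortholog map.

    Keeps only orthologs valid in both species.  Returns a frame indexed by
    ``gene_id_a`` with columns value_a / value_b / gene_id_b / d (= a - b).
    """
    df = orthologs.copy()
    df["value_a"] = signals_a["value"].reindex(df["gene_id_a"]).to_numpy()
    df["valid_a"] = signals_a["valid"].reindex(df["gene_id_a"]).fillna(False).to_numpy()
    df["value_b"] = signals_b["value"].reindex(df["gene_id_b"]).to_numpy()
    df["valid_b"] = signals_b["valid"].reindex(df["gene_id_b"]).fillna(False).to_numpy()
    df = df[df["valid_a"].astype(bool) & df["valid_b"].astype(bool)]
    if df.empty:
        raise ValueError("no orthologs valid in both species")
    df["d"] = df["value_a"] - df["value_b"]
    out = df.set_index("gene_id_a")[["gene_id_b", "value_a", "value_b", "d"]]
    out.attrs["region"] = region
    return out


def interspecies_profile_correlation(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-bin and overall Pearson correlation of juxtaposed profiles.

    Both matrices must share row order (orthologs, one species' ids
    re-indexed to the other's) and columns (window bins).
    """
    if len(matrix_a) != len(matrix_b):
        raise ValueError("matrices must pair the same orthologs row-by-row")
    if len(matrix_a) < 3:
        raise ValueError("need at least 3 paired genes")
    a = matrix_a.to_numpy()
    b = matrix_b.to_numpy()
    per_bin = {}
    for j, col in enumerate(matrix_a.columns):
        x, y = a[:, j], b[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        per_bin[col] = (
            float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() >= 3 else np.nan
        )
    ok = ~(np.isnan(a) | np.isnan(b))
    overall = float(np.corrcoef(a[ok].ravel(), b[ok].ravel())[0, 1])
    return pd.Series(per_bin), overall


def divergence_exceedance(
    differences: pd.Series | np.ndarray, thresholds: np.ndarray = DEFAULT_GRID
) -> pd.Series:
    """Percent of genes with |d| exceeding each threshold (nonincreasing)."""
    d = np.abs(np.asarray(differences, dtype=float))
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no differences")
    return pd.Series(
        {float(t): float(100.0 * (d > t).mean()) for t in thresholds}
    )


def lowess_divergent_genes(
    x: pd.Series,
    y: pd.Series,
    n_per_side: int = 800,
    span: float = 0.3,
    iterations: int = 2,
) -> tuple[list[str], list[str]]:
    """Most divergent genes by residual from a Lowess fit of y on x.

    Returns ``(set_a_high, set_b_high)``: the ``n_per_side`` most negative
    residuals (species A above the curve) and most positive residuals
    (species B above).  Ties break by gene id; the sets are disjoint.
    """
    idx = x.index.intersection(y.index)
    x, y = x.loc[idx], y.loc[idx]
    if len(idx) < 2 * n_per_side:
        raise ValueError("n_per_side too large for the number of genes")
    fitted = sm_lowess(
        y.to_numpy(), x.to_numpy(), frac=span, it=iterations,
        xvals=x.to_numpy(),
    )
    resid = pd.Series(y.to_numpy() - fitted, index=idx)
    order = resid.sort_index(kind="stable").sort_values(kind="stable")
    set_a_high = list(order.index[:n_per_side])  # most negative residuals
    set_b_high = list(order.index[-n_per_side:])
    return set_a_high, set_b_high


def classify_change_pair(
    d1: pd.Series, d2: pd.Series, threshold: float = CHANGE_THRESHOLD
) -> tuple[pd.Series, pd.Series]:
    """Classify paired log2 differences into co-change categories.

    Per gene: ``none`` (neither |d| above threshold), ``only_first``,
    ``only_second``, ``consistent`` (both above, same sign), ``opposite``
    (both above, opposite sign).  Returns (labels, proportions); the
    proportions sum to 1.
    """
    idx = d1.index.intersection(d2.index)
    a = d1.loc[idx].to_numpy(dtype=float)
    b = d2.loc[idx].to_numpy(dtype=float)
    sig1 = np.abs(a) > threshold
    sig2 = np.abs(b) > threshold
    labels = np.full(len(idx), "none", dtype=object)
    labels[sig1 & ~sig2] = "only_first"
    labels[~sig1 & sig2] = "only_second"
    both = sig1 & sig2
    labels[both & (np.sign(a) == np.sign(b))] = "consistent"
    labels[both & (np.sign(a) != np.sign(b))] = "opposite"
    ser = pd.Series(labels, index=idx, name="pair_class")
    props = ser.value_counts(normalize=True).reindex(PAIR_CLASSES, fill_value=0.0)
    return ser, props


def threshold_gated_correlation(
    d_expr: pd.Series, d_mod: pd.Series, threshold: float = CHANGE_THRESHOLD
) -> float:
    """Pearson r over genes where both changes exceed the threshold."""
    idx = d_expr.index.intersection(d_mod.index)
    e = d_expr.loc[idx]
    m = d_mod.loc[idx]
    gate = (e.abs() > threshold) & (m.abs() > threshold)
    if gate.sum() < 3:
        raise ValueError("fewer than 3 genes pass the significance gate")
    return float(e[gate].corr(m[gate]))


def consistency_vs_threshold(
    d_expr: pd.Series,
    d_mod: pd.Series,
    expr_threshold: float = CHANGE_THRESHOLD,
    mod_threshold_grid: np.ndarray = DEFAULT_GRID,
) -> pd.Series:
    """Percent of gated genes whose changes share a sign, per mod threshold.

    At each threshold t the gate is |d_expr| > expr_threshold and
    |d_mod| > t; empty gates give NaN.
    """
    idx = d_expr.index.intersection(d_mod.index)
    e = d_expr.loc[idx].to_numpy(dtype=float)
    m = d_mod.loc[idx].to_numpy(dtype=float)
    e_sig = np.abs(e) > expr_threshold
    out = {}
    for t in mod_threshold_grid:
        gate = e_sig & (np.abs(m) > t)
        if gate.sum() == 0:
            out[float(t)] = np.nan
        else:
            out[float(t)] = float(
                100.0 * (np.sign(e[gate]) == np.sign(m[gate])).mean()
            )
    return pd.Series(out)


def divergent_enrichment_curve(
    d_expr: pd.Series,
    d_mod: pd.Series,
    n_extreme: int = 1000,
    mod_threshold_grid: np.ndarray = DEFAULT_GRID,
) -> pd.Series:
    """Fold enrichment of expression-divergent over non-divergent genes.

    ``divergent`` / ``non-divergent`` are the ``n_extreme`` genes with the
    largest / smallest |d_expr|.  At each modification threshold t the fold
    is (divergent genes with |d_mod| > t) / (non-divergent genes with
    |d_mod| > t); zero denominators give NaN.
    """
    idx = d_expr.index.intersection(d_mod.index)
    if len(idx) < 2 * n_extreme:
        raise ValueError("n_extreme too large for the number of genes")
    e_abs = d_expr.loc[idx].abs().sort_index(kind="stable").sort_values(kind="stable")
    non_div = e_abs.index[:n_extreme]
    div = e_abs.index[-n_extreme:]
    m_div = d_mod.loc[div].abs().to_numpy()
    m_non = d_mod.loc[non_div].abs().to_numpy()
    out = {}
    for t in mod_threshold_grid:
        num = (m_div > t).sum()
        den = (m_non > t).sum()
        out[float(t)] = float(num / den) if den else np.nan
    return pd.Series(out)


def triple_classification(
    d_ac: pd.Series,
    d_me: pd.Series,
    d_expr: pd.Series,
    threshold: float = CHANGE_THRESHOLD,
) -> tuple[pd.Series, pd.Series]:
    """Joint classification of H3K9ac, H3K4me3 and expression changes.

    Labels: ``none`` (no significant change in any), ``all_consistent``
    (all three significant, same sign), ``ac_me_not_expr`` (acetylation and
    methylation consistent, expression not part of the consensus),
    ``ac_expr_not_me``, ``me_expr_not_ac``, and a residual ``other`` for
    the remaining sign/threshold combinations.  Returns (labels,
    proportions).
    """
    idx = d_ac.index.intersection(d_me.index).intersection(d_expr.index)
    a = d_ac.loc[idx].to_numpy(dtype=float)
    m = d_me.loc[idx].to_numpy(dtype=float)
    e = d_expr.loc[idx].to_numpy(dtype=float)
    sa, sm_, se = (np.abs(v) > threshold for v in (a, m, e))

    def consistent(x, sx, y, sy):
        return sx & sy & (np.sign(x) == np.sign(y))

    am = consistent(a, sa, m, sm_)
    ae = consistent(a, sa, e, se)
    me_ = consistent(m, sm_, e, se)

    labels = np.full(len(idx), "other", dtype=object)
    labels[~sa & ~sm_ & ~se] = "none"
    labels[am & ~ (am & ae & me_) ] = "ac_me_not_expr"
    labels[ae & ~(am & ae & me_)] = "ac_expr_not_me"
    labels[me_ & ~(am & ae & me_)] = "me_expr_not_ac"
    labels[am & ae & me_] = "all_consistent"
    ser = pd.Series(labels, index=idx, name="triple_class")
    props = ser.value_counts(normalize=True).reindex(TRIPLE_CLASSES, fill_value=0.0)
    return ser, props
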