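"""Interspecies comparison: pairing, exceedance, Lowess extraction,
co-change classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromdiverge import divergence as dive


def _series(values, prefix="g"):
    idx = pd.Index([f"{prefix}{i:04d}" for i in range(len(values))],
                   name="gene_id")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def _signals(values, ids):
    return pd.DataFrame({"value": values, "valid": True},
                        index=pd.Index(ids, name="gene_id"))


def test_paired_region_signals_differences():
    ids_a = [f"a{i}" for i in range(5)]
    ids_b = [f"b{i}" for i in range(5)]
    orth = pd.DataFrame({"gene_id_a": ids_a, "gene_id_b": ids_b})
    sa = _signals([1.0, 2, 3, 4, 5], ids_a)
    sb = _signals([1.0, 2, 3, 4, 5], ids_b)
    out = dive.paired_region_signals(sa, sb, orth)
    assert (out["d"] == 0).all()

    sb2 = _signals([0.0, 1, 2, 3, 4], ids_b)
    out = dive.paired_region_signals(sa, sb2, orth)
    assert (out["d"] == 1).all()

    sa.loc["a0", "valid"] = False
    out = dive.paired_region_signals(sa, sb, orth)
    assert "a0" not in out.index and len(out) == 4


def test_interspecies_profile_correlation_extremes():
    rng = np.random.default_rng(1)
    a = pd.DataFrame(rng.normal(size=(100, 10)))
    per_bin, overall = dive.interspecies_profile_correlation(a, a)
    np.testing.assert_allclose(per_bin, 1.0)
    assert overall == pytest.approx(1.0)

    per_bin, overall = dive.interspecies_profile_correlation(a, -a)
    np.testing.assert_allclose(per_bin, -1.0)
    assert overall == pytest.approx(-1.0)

    b = pd.DataFrame(rng.normal(size=(500, 10)))
    c = pd.DataFrame(rng.normal(size=(500, 10)))
    per_bin, _ = dive.interspecies_profile_correlation(b, c)
    assert (per_bin.abs() < 0.15).all()


def test_divergence_exceedance_closed_form():
    zeros = _series(np.zeros(100))
    curve = dive.divergence_exceedance(zeros, np.array([0.0, 0.5, 1.0]))
    assert curve[0.5] == 0.0 and curve[1.0] == 0.0

    rng = np.random.default_rng(2)
    sigma = 0.7
    d = _series(rng.normal(0, sigma, 200_000))
    curve = dive.divergence_exceedance(d, np.array([0.0, sigma]))
    assert curve[0.0] == pytest.approx(100.0)
    expected = 100 * 2 * (1 - sps.norm.cdf(1.0))  # ~31.73%
    assert curve[sigma] == pytest.approx(expected, abs=0.7)

    mono = dive.divergence_exceedance(d)
    assert (np.diff(mono.to_numpy()) <= 0).all()


def test_lowess_outlier_is_rank_one():
    rng = np.random.default_rng(3)
    x = _series(np.linspace(0, 10, 200))
    y = x.copy()
    y.iloc[57] += 3.0  # single strong positive outlier
    a_high, b_high = dive.lowess_divergent_genes(x, y, n_per_side=10)
    assert b_high[-1] == y.index[57]
    assert y.index[57] not in a_high

    # mirror symmetry: swapping species swaps the two sets
    a2, b2 = dive.lowess_divergent_genes(y, x, n_per_side=10)
    assert y.index[57] == a2[0]

    with pytest.raises(ValueError, match="n_per_side"):
        dive.lowess_divergent_genes(x, y, n_per_side=150)


def test_classify_change_pair_categories_and_proportions():
    d1 = _series([0.0, 0.5, -0.5, 0.5, 0.2])
    d2 = _series([0.0, 0.5, 0.5, -0.5, 0.9])
    labels, props = dive.classify_change_pair(d1, d2, threshold=0.4)
    assert list(labels) == ["none", "consistent", "opposite", "opposite",
                            "only_second"]
    assert props.sum() == pytest.approx(1.0)

    # species swap: every d negates, categories stable
    labels2, props2 = dive.classify_change_pair(-d1, -d2, threshold=0.4)
    pd.testing.assert_series_equal(labels, labels2, check_names=False)
    pd.testing.assert_series_equal(props, props2)


def test_threshold_gated_correlation():
    rng = np.random.default_rng(4)
    d = _series(rng.normal(0, 1, 500))
    assert dive.threshold_gated_correlation(d, d) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="fewer than 3"):
        dive.threshold_gated_correlation(_series([0.0] * 10), _series([0.0] * 10))


def test_consistency_vs_threshold_extremes():
    rng = np.random.default_rng(5)
    d = _series(rng.normal(0, 1, 2000))
    grid = np.array([0.4, 0.6, 0.8, 1.0])
    same = dive.consistency_vs_threshold(d, d, 0.4, grid)
    assert (same == 100.0).all()
    opp = dive.consistency_vs_threshold(d, -d, 0.4, grid)
    assert (opp == 0.0).all()

    other = _series(rng.normal(0, 1, 2000))
    null = dive.consistency_vs_threshold(d, other, 0.4, np.array([0.4]))
    assert abs(null.iloc[0] - 50.0) < 10.0  # independent signs ~ 50%


def test_divergent_enrichment_curve():
    rng = np.random.default_rng(6)
    d_expr = _series(rng.normal(0, 1, 4000))
    d_ind = _series(rng.normal(0, 1, 4000))
    null = dive.divergent_enrichment_curve(d_expr, d_ind, 1000,
                                           np.array([0.2, 0.5]))
    assert null.between(0.7, 1.4).all()  # fold ~ 1 under independence

    coupled = dive.divergent_enrichment_curve(d_expr, d_expr, 1000,
                                              np.array([0.5, 1.0, 1.5]))
    assert coupled.dropna().gt(2.0).all()
    assert coupled.dropna().is_monotonic_increasing

    with pytest.raises(ValueError, match="n_extreme"):
        dive.divergent_enrichment_curve(d_expr, d_ind, 3000)


def _triple_oracle(a, m, e, t=0.4):
    """Independent truth table for the triple classification."""
    sa, sm, se = abs(a) > t, abs(m) > t, abs(e) > t
    if not (sa or sm or se):
        return "none"
    same = lambda x, y: np.sign(x) == np.sign(y)
    if sa and sm and se and same(a, m) and same(m, e):
        return "all_consistent"
    if sa and sm and same(a, m):
        return "ac_me_not_expr"
    if sa and se and same(a, e):
        return "ac_expr_not_me"
    if sm and se and same(m, e):
        return "me_expr_not_ac"
    return "other"


def test_triple_classification_against_enumeration_oracle():
    vals = [-1.0, 0.0, 1.0]  # below/above the 0.4 threshold, both signs
    rows = [(a, m, e) for a in vals for m in vals for e in vals]
    d_ac = _series([r[0] for r in rows])
    d_me = _series([r[1] for r in rows])
    d_expr = _series([r[2] for r in rows])
    labels, props = dive.triple_classification(d_ac, d_me, d_expr, threshold=0.4)
    expected = [_triple_oracle(*r) for r in rows]
    assert list(labels) == expected
    assert props.sum() == pytest.approx(1.0)
    assert labels.loc[d_ac.index[0]] == "all_consistent"  # (-1,-1,-1)
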