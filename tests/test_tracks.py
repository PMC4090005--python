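"""Strand profiles, fragment-length scan, merging, normalization, smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdiverge import tracks as trk
from chromdiverge.io import AlignedRead, CoverageTrack


def _profile(values, strand="+"):
    arr = np.asarray(values, dtype=np.int64)
    return trk.StrandProfile({"chrI": arr}, strand, int(arr.sum()))


def test_build_strand_profiles_counts_first_bases():
    reads = [AlignedRead("chrI", 5, "+")] * 3 + [AlignedRead("chrI", 7, "-")]
    fwd, rev = trk.build_strand_profiles(reads, {"chrI": 10})
    assert fwd.data["chrI"][5] == 3 and fwd.total_reads == 3
    assert rev.data["chrI"][7] == 1 and rev.total_reads == 1

    fwd0, rev0 = trk.build_strand_profiles([], {"chrI": 10})
    assert fwd0.data["chrI"].sum() == 0 and rev0.data["chrI"].sum() == 0


def test_build_strand_profiles_rejects_out_of_bounds():
    reads = pd.DataFrame({"chrom": ["chrI"], "pos": [10], "strand": ["+"]})
    with pytest.raises(ValueError, match="bounds"):
        trk.build_strand_profiles(reads, {"chrI": 10})


def test_fragment_length_identity_profile():
    rng = np.random.default_rng(0)
    v = rng.poisson(2.0, 500)
    off, corr = trk.estimate_fragment_length(_profile(v), _profile(v, "-"), 50)
    assert off == 0 and corr == pytest.approx(1.0)


def test_fragment_length_matches_brute_force_spearman_oracle():
    rng = np.random.default_rng(42)
    fwd_v = rng.poisson(3.0, 800)
    rev_v = np.zeros_like(fwd_v)
    rev_v[100:] = fwd_v[:-100]  # delay by exactly 100 bp
    fwd, rev = _profile(fwd_v), _profile(rev_v, "-")
    max_shift = 150
    off, corr = trk.estimate_fragment_length(fwd, rev, max_shift)
    assert off == 100

    # independent oracle: scipy.spearmanr at every shift
    best = max(
        range(max_shift + 1),
        key=lambda s: stats.spearmanr(fwd_v[: len(fwd_v) - s or None],
                                      rev_v[s:]).statistic,
    )
    oracle_corr = stats.spearmanr(fwd_v[:-100], rev_v[100:]).statistic
    assert off == best
    assert corr == pytest.approx(oracle_corr, abs=1e-12)


def test_fragment_length_constant_profile_errors():
    with pytest.raises(ValueError, match="constant"):
        trk.estimate_fragment_length(_profile(np.zeros(100, dtype=int)),
                                     _profile(np.ones(100, dtype=int), "-"), 10)


def test_merge_strands_hand_example():
    fwd_v = np.zeros(400, dtype=np.int64)
    rev_v = np.zeros(400, dtype=np.int64)
    fwd_v[100] = 1
    rev_v[224] = 1
    track = trk.merge_strands(_profile(fwd_v), _profile(rev_v, "-"), offset=124)
    assert track.data["chrI"][162] == 2
    assert track.data["chrI"].sum() == 2

    t0 = trk.merge_strands(_profile(fwd_v), _profile(rev_v, "-"), offset=0)
    np.testing.assert_array_equal(t0.data["chrI"], fwd_v + rev_v)


def test_merge_strands_conserves_mass_with_counted_edge_losses():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(50, 300))
        fwd_v = rng.poisson(1.0, n)
        rev_v = rng.poisson(1.0, n)
        offset = int(rng.integers(0, 60))
        track = trk.merge_strands(_profile(fwd_v), _profile(rev_v, "-"), offset)
        total_in = fwd_v.sum() + rev_v.sum()
        assert track.total() + track.meta["edge_lost"] == pytest.approx(total_in)


def test_normalize_to_lowest_total():
    t1 = CoverageTrack({"chrI": np.full(10, 10.0)})  # total 100
    t2 = CoverageTrack({"chrI": np.full(10, 20.0)})  # total 200
    out = trk.normalize_to_lowest_total([t1, t2])
    assert out[0].total() == pytest.approx(100)
    np.testing.assert_allclose(out[1].data["chrI"], np.full(10, 10.0))

    single = trk.normalize_to_lowest_total([t1])
    np.testing.assert_array_equal(single[0].data["chrI"], t1.data["chrI"])

    rng = np.random.default_rng(3)
    tracks = [CoverageTrack({"chrI": rng.random(50) + 0.1}) for _ in range(5)]
    outs = trk.normalize_to_lowest_total(tracks)
    lowest = min(t.total() for t in tracks)
    for t in outs:
        assert abs(t.total() - lowest) / lowest < 1e-9

    with pytest.raises(ValueError, match="zero total"):
        trk.normalize_to_lowest_total([CoverageTrack({"chrI": np.zeros(5)})])


def test_log2_track_values_and_monotonicity():
    t = CoverageTrack({"chrI": np.array([0.0, 3.0, 1.0])})
    lg = trk.log2_track(t, pseudocount=1.0)
    np.testing.assert_allclose(lg.data["chrI"], [0.0, 2.0, 1.0])
    assert lg.scale == "log2"
    with pytest.raises(ValueError, match="already log2"):
        trk.log2_track(lg)

    rng = np.random.default_rng(1)
    a = rng.random(100) * 10
    b = a + rng.random(100)  # strictly higher
    la = trk.log2_track(CoverageTrack({"c": a})).data["c"]
    lb = trk.log2_track(CoverageTrack({"c": b})).data["c"]
    assert (lb > la).all()


def test_smooth_track_constant_delta_and_conservation():
    const = CoverageTrack({"chrI": np.full(500, 4.2)})
    np.testing.assert_allclose(trk.smooth_track(const, 140).data["chrI"], 4.2)

    delta = np.zeros(1001)
    delta[500] = 141.0
    sm = trk.smooth_track(CoverageTrack({"chrI": delta}), 141).data["chrI"]
    np.testing.assert_allclose(sm[430:571], 1.0)
    assert sm[429] == 0.0 and sm[571] == 0.0

    # mass conserved when the signal sits away from chromosome edges
    rng = np.random.default_rng(5)
    v = np.zeros(800)
    v[200:600] = rng.random(400)
    sm = trk.smooth_track(CoverageTrack({"chrI": v}), 99).data["chrI"]
    assert sm.sum() == pytest.approx(v.sum())

    with pytest.raises(ValueError, match="larger than chromosome"):
        trk.smooth_track(CoverageTrack({"chrI": np.zeros(50)}), 140)


def test_h3_normalize_subtracts_elementwise():
    rng = np.random.default_rng(9)
    mod_lin = CoverageTrack({"chrI": rng.random(100) * 5})
    mod = trk.log2_track(mod_lin)
    same = trk.h3_normalize(mod, mod)
    np.testing.assert_allclose(same.data["chrI"], 0.0)

    h3 = mod.copy()
    h3.data["chrI"] = np.full(100, 1.5)
    out = trk.h3_normalize(mod, h3)
    np.testing.assert_allclose(out.data["chrI"], mod.data["chrI"] - 1.5)

    with pytest.raises(ValueError, match="log2"):
        trk.h3_normalize(mod_lin, h3)
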