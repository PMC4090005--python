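"""From stranded read positions to normalized per-base coverage tracks.

The fragment length of a single-end ChIP sample is estimated by scoring
the first sequenced base of every read on separate forward / reverse
strand profiles, then shifting the reverse profile one base at a time and
taking the offset that maximizes the rank correlation between strands.
The two profiles are then shifted towards each other by half that offset
and summed, samples are normalized to the lowest library total, log2
transformed, and (for the H3 occupancy control) smoothed with a centered
moving window before being subtracted from the modification tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from chromdiverge.io import AlignedRead, CoverageTrack

#: Default moving-window width (bases) for smoothing the H3 track; even
#: values are centered by widening to the next odd width (140 -> 141).
H3_SMOOTH_WINDOW = 140


@dataclass
class StrandProfile:
    """Per-chromosome counts of first sequenced bases on one strand."""

    data: dict[str, np.ndarray]
    strand: str
    total_reads: int = 0

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.data])


def build_strand_profiles(
    reads: pd.DataFrame | Iterable[AlignedRead],
    chrom_sizes: dict[str, int],
) -> tuple[StrandProfile, StrandProfile]:
    """Score the first sequenced base of every read per strand.

    ``reads`` is either a DataFrame with columns chrom/pos/strand or an
    iterable of :class:`AlignedRead`.  Out-of-bounds reads raise.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = pd.DataFrame(
            [(r.chrom, r.pos, r.strand) for r in reads],
            columns=["chrom", "pos", "strand"],
        )
    fwd = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    rev = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    totals = {"+": 0, "-": 0}
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        pos = sub["pos"].to_numpy()
        n = chrom_sizes[chrom]
        if pos.size and (pos.min() < 0 or pos.max() >= n):
            raise ValueError(f"read position out of bounds on {chrom}")
        target = fwd if strand == "+" else rev
        target[chrom] += np.bincount(pos, minlength=n)
        totals[strand] += len(sub)
    return (
        StrandProfile(fwd, "+", totals["+"]),
        StrandProfile(rev, "-", totals["-"]),
    )


def _ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), fast path for small nonnegative integers."""
    if np.issubdtype(x.dtype, np.integer) and x.size and 0 <= x.min():
        vmax = int(x.max())
        if vmax < 1_000_000:
            counts = np.bincount(x, minlength=vmax + 1)
            below = np.concatenate(([0], np.cumsum(counts)[:-1]))
            rank_of_value = below + (counts + 1) / 2.0
            return rank_of_value[x]
    return stats.rankdata(x)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def estimate_fragment_length(
    fwd: StrandProfile,
    rev: StrandProfile,
    max_shift: int = 400,
    method: str = "spearman",
) -> tuple[int, float]:
    """Estimate the average fragment length from strand cross-correlation.

    For each shift s in [0, max_shift] the reverse profile is shifted left
    by s (per chromosome, then concatenated) and correlated with the
    forward profile; the argmax shift is returned with its correlation.
    Ties break toward the smaller shift.  ``method`` is ``"spearman"``
    (rank correlation, the default) or ``"pearson"``.

    Raises ``ValueError`` on constant (zero-variance) profiles.
    """
    chroms = list(fwd.data)
    f_arrays = [np.asarray(fwd.data[c]) for c in chroms]
    r_arrays = [np.asarray(rev.data[c]) for c in chroms]
    if all(np.ptp(a) == 0 for a in f_arrays) or all(np.ptp(a) == 0 for a in r_arrays):
        raise ValueError("constant strand profile: cannot estimate fragment length")

    best_shift, best_corr = 0, -np.inf
    for s in range(max_shift + 1):
        f_parts, r_parts = [], []
        for fa, ra in zip(f_arrays, r_arrays):
            if len(fa) <= s:
                continue
            f_parts.append(fa[: len(fa) - s] if s else fa)
            r_parts.append(ra[s:])
        if not f_parts:
            break
        f_cat = np.concatenate(f_parts)
        r_cat = np.concatenate(r_parts)
        if method == "spearman":
            corr = _pearson(_ranks(f_cat), _ranks(r_cat))
        elif method == "pearson":
            corr = _pearson(f_cat.astype(float), r_cat.astype(float))
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if np.isfinite(corr) and corr > best_corr:
            best_shift, best_corr = s, corr
    return best_shift, best_corr


def merge_strands(
    fwd: StrandProfile, rev: StrandProfile, offset: int, name: str = ""
) -> CoverageTrack:
    """Shift the strands towards each other by half the offset and sum.

    Forward counts move right by floor(offset/2), reverse counts move left
    by the remainder; counts shifted past a chromosome edge are dropped and
    tallied in ``meta["edge_lost"]``.  Output is a linear-scale track.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    h = offset // 2
    r = offset - h
    data: dict[str, np.ndarray] = {}
    lost = 0.0
    for chrom, f in fwd.data.items():
        rv = rev.data[chrom]
        n = len(f)
        out = np.zeros(n, dtype=float)
        if h < n:
            out[h:] += f[: n - h]
            lost += f[n - h:].sum()
        else:
            lost += f.sum()
        if r < n:
            out[: n - r] += rv[r:]
            lost += rv[:r].sum()
        else:
            lost += rv.sum()
        data[chrom] = out
    return CoverageTrack(
        data=data,
        name=name,
        scale="linear",
        fragment_length=offset,
        meta={"edge_lost": float(lost)},
    )


def normalize_to_lowest_total(tracks: list[CoverageTrack]) -> list[CoverageTrack]:
    """Scale every linear track so its total equals the lowest library total."""
    if not tracks:
        raise ValueError("no tracks to normalize")
    totals = []
    for t in tracks:
        if t.scale != "linear":
            raise ValueError(f"track {t.name!r} is not linear scale")
        tot = t.total()
        if tot <= 0:
            raise ValueError(f"track {t.name!r} has zero total")
        totals.append(tot)
    lowest = min(totals)
    out = []
    for t, tot in zip(tracks, totals):
        s = t.copy()
        factor = lowest / tot
        for c in s.data:
            s.data[c] *= factor
        s.meta["normalized_to"] = lowest
        out.append(s)
    return out


def log2_track(track: CoverageTrack, pseudocount: float = 1.0) -> CoverageTrack:
    """log2(value + pseudocount); flips the scale flag to ``log2``."""
    if track.scale == "log2":
        raise ValueError(f"track {track.name!r} is already log2 scale")
    out = track.copy()
    for c in out.data:
        out.data[c] = np.log2(out.data[c] + pseudocount)
    out.scale = "log2"
    out.meta["pseudocount"] = pseudocount
    return out


def smooth_track(track: CoverageTrack, window: int = H3_SMOOTH_WINDOW) -> CoverageTrack:
    """Centered moving mean; even windows widen by one base to center.

    Edge windows are truncated to the available bases.  Raises if the
    window exceeds the shortest chromosome.
    """
    w = window if window % 2 == 1 else window + 1
    half = w // 2
    out = track.copy()
    for chrom, v in out.data.items():
        n = len(v)
        if w > n:
            raise ValueError(f"window {w} larger than chromosome {chrom} ({n} bp)")
        c = np.concatenate(([0.0], np.cumsum(v, dtype=float)))
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        out.data[chrom] = (c[hi] - c[lo]) / (hi - lo)
    out.meta["smooth_window"] = w
    return out


def h3_normalize(mod: CoverageTrack, h3: CoverageTrack) -> CoverageTrack:
    """Subtract the (log2, smoothed) H3 track from a log2 modification track."""
    if mod.scale != "log2" or h3.scale != "log2":
        raise ValueError("h3_normalize requires both tracks in log2 scale")
    if set(mod.data) != set(h3.data):
        raise ValueError("chromosome sets differ between modification and H3 tracks")
    out = mod.copy()
    for c in out.data:
        out.data[c] = out.data[c] - h3.data[c]
    out.meta["h3_normalized"] = True
    out.name = f"{mod.name}-h3norm"
    return out
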