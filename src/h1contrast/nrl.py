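"""Nucleosome repeat length (NRL) estimation from dyad distance spectra.

The phasogram approach: count all same-region ordered dyad pairs by their
distance (1 bp resolution, up to ``max_distance``), smooth the normalized
frequency spectrum, locate the periodic summits, and regress summit
position on peak order k.  The slope of that line is the NRL — the average
dyad-to-dyad spacing of adjacent nucleosomes — robust to missed summits
only insofar as consecutive detected peaks remain consecutive multiples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import IntervalSet


@dataclass
class DistanceHistogram:
    max_distance: int
    counts: np.ndarray       # index d-1 holds count for distance d
    frequency: np.ndarray    # counts / total
    smoothed: Optional[np.ndarray] = None

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, self.max_distance + 1)


@dataclass
class NRLFit:
    summit_positions: np.ndarray  # bp, one per peak order k = 1..K
    slope: float                  # the NRL, bp
    intercept: float              # bp
    r_squared: float


def distance_histogram(dyads: IntervalSet, regions: IntervalSet,
                       max_distance: int = 1000) -> DistanceHistogram:
    """Histogram of all same-region dyad pair distances in [1, max_distance].

    Dyads are taken as point positions (interval centers).  Every ordered
    pair within one region counts once, so the spectrum carries summits at
    all multiples of the repeat length, not only the first.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    counts = np.zeros(max_distance, dtype=np.int64)
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, ivs in dyads.by_chrom().items():
        pos_by_chrom[chrom] = np.array(sorted(iv.center for iv in ivs))
    for region in regions:
        pos = pos_by_chrom.get(region.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        p = pos[lo:hi]
        for i in range(len(p)):
            # partner dyads within max_distance downstream of p[i]
            j_hi = np.searchsorted(p, p[i] + max_distance, side="right")
            d = p[i + 1:j_hi] - p[i]
            d = d[d >= 1]
            np.add.at(counts, d - 1, 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no qualifying dyad pairs: empty histogram")
    return DistanceHistogram(max_distance, counts, counts / total)


def find_summits(hist: DistanceHistogram, smooth_window: int = 21,
                 min_separation: int = 100,
                 min_prominence_frac: float = 0.05) -> np.ndarray:
    """Summit positions (bp) of the smoothed distance spectrum.

    Savitzky-Golay smoothing (polynomial order 3) then local maxima at
    least ``min_separation`` bp apart with prominence above
    ``min_prominence_frac`` of the smoothed range, in increasing distance
    order.  Raises when fewer than 2 summits are found.
    """
    if smooth_window % 2 == 0:
        smooth_window += 1
    freq = hist.frequency
    if smooth_window >= 5 and len(freq) > smooth_window:
        sm = savgol_filter(freq, smooth_window, polyorder=3)
    else:
        sm = freq.copy()
    hist.smoothed = sm
    # height floor excludes flat plateaus that smoothing side lobes would
    # otherwise promote to (low) local maxima
    prominence = min_prominence_frac * (sm.max() - sm.min())
    idx, _ = find_peaks(sm, distance=min_separation, prominence=prominence,
                        height=min_prominence_frac * sm.max())
    summits = hist.distances[idx].astype(float)
    if len(summits) < 2:
        raise ValueError(
            f"found {len(summits)} summit(s); >= 2 needed for an NRL fit")
    return summits


def fit_nrl(summits: np.ndarray) -> NRLFit:
    """OLS of summit position on peak order k = 1..K; the slope is the NRL."""
    summits = np.asarray(summits, dtype=float)
    if len(summits) < 2:
        raise ValueError("need >= 2 summits")
    k = np.arange(1, len(summits) + 1, dtype=float)
    slope, intercept = np.polyfit(k, summits, 1)
    pred = slope * k + intercept
    ss_res = float(np.sum((summits - pred) ** 2))
    ss_tot = float(np.sum((summits - summits.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NRLFit(summits, float(slope), float(intercept), r2)


def estimate_nrl(dyads: IntervalSet, regions: IntervalSet,
                 max_distance: int = 1000, smooth_window: int = 21,
                 min_separation: int = 100) -> NRLFit:
    """Distance histogram -> summits -> linear fit, in one call."""
    hist = distance_histogram(dyads, regions, max_distance)
    summits = find_summits(hist, smooth_window, min_separation)
    return fit_nrl(summits)
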