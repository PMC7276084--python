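"""Binned signal tracks: coverage, smoothing, Input normalization,
replicate statistics and genome-wide pairwise correlation.

A :class:`SignalTrack` holds one non-negative array per chromosome at a
fixed bin size, plus condition metadata (protocol, H1 variant, replicate).
Replicate consistency is summarised per window by the relative standard
deviation (RSD = sd/mean, sample sd with n-1 denominator), the filter used
to gate all downstream window comparisons.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import BedParseError, Genome, IntervalSet, PathLike

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackMeta:
    protocol: str = "other"   # xChIP | xxChIP | Input | other
    variant: str = "other"    # H1.2 | H1.5 | Input | other
    replicate: Optional[int] = None

    def label(self) -> str:
        rep = f"_rep{self.replicate}" if self.replicate is not None else ""
        return f"{self.protocol}_{self.variant}{rep}"


def _n_bins(chrom_size: int, bin_size: int) -> int:
    return math.ceil(chrom_size / bin_size)


@dataclass
class SignalTrack:
    genome: Genome
    bin_size: int
    values: dict[str, np.ndarray]
    meta: TrackMeta = field(default_factory=TrackMeta)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, size in self.genome.chrom_sizes.items():
            want = _n_bins(size, self.bin_size)
            arr = self.values.get(chrom)
            if arr is None:
                self.values[chrom] = np.zeros(want)
            elif len(arr) != want:
                raise ValueError(
                    f"{chrom}: expected {want} bins, got {len(arr)}"
                )

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))

    def copy_with(self, values: dict[str, np.ndarray],
                  meta: Optional[TrackMeta] = None) -> "SignalTrack":
        return SignalTrack(self.genome, self.bin_size,
                           {c: np.asarray(v, dtype=float) for c, v in values.items()},
                           meta if meta is not None else self.meta)


@dataclass
class WindowStats:
    """Per-window replicate mean and RSD at a fixed window size.

    Windows tile each chromosome (window w spans [w*window, (w+1)*window));
    ``defined`` is False where the window mean is zero, in which case RSD is
    meaningless and the window is excluded downstream.
    """

    genome: Genome
    window: int
    mean: dict[str, np.ndarray]
    rsd: dict[str, np.ndarray]
    defined: dict[str, np.ndarray]


def bin_coverage(intervals: IntervalSet, genome: Genome, bin_size: int,
                 meta: Optional[TrackMeta] = None) -> SignalTrack:
    """Count interval bases per bin (an interval split over a bin boundary
    contributes its within-bin bases to each bin)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values = {c: np.zeros(_n_bins(s, bin_size))
              for c, s in genome.chrom_sizes.items()}
    for iv in intervals:
        if iv.chrom not in values:
            continue
        arr = values[iv.chrom]
        end = min(iv.end, genome.chrom_sizes[iv.chrom])
        b0, b1 = iv.start // bin_size, (end - 1) // bin_size
        if b0 == b1:
            arr[b0] += end - iv.start
            continue
        arr[b0] += (b0 + 1) * bin_size - iv.start
        arr[b1] += end - b1 * bin_size
        if b1 > b0 + 1:
            arr[b0 + 1:b1] += bin_size
    return SignalTrack(genome, bin_size, values,
                       meta if meta is not None else TrackMeta())


def smooth_running(track: SignalTrack, window: int) -> SignalTrack:
    """Centered running mean over ``window`` bp; edges use the truncated
    available window (mean of fewer bins, never zero-padded)."""
    if window < track.bin_size:
        raise ValueError("smoothing window must be >= bin_size")
    if window % track.bin_size != 0:
        raise ValueError("smoothing window must be a multiple of bin_size")
    w = window // track.bin_size
    out = {}
    kernel = np.ones(w)
    for chrom, v in track.values.items():
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        out[chrom] = sums / counts
    return track.copy_with(out)


def normalize_by_input(signal: SignalTrack, input_: SignalTrack,
                       pseudocount: float = 1.0) -> SignalTrack:
    """Signal/Input ratio per bin after library-size scaling.

    Both tracks are first scaled to the mean of their two totals, then the
    ratio (signal + pseudocount) / (input + pseudocount) is taken per bin.
    """
    if signal.bin_size != input_.bin_size or \
            signal.genome.chrom_sizes != input_.genome.chrom_sizes:
        raise ValueError("signal and input tracks must share genome and bin size")
    ts, ti = signal.total(), input_.total()
    if ts <= 0 or ti <= 0:
        raise ValueError("cannot library-scale a zero-total track")
    target = 0.5 * (ts + ti)
    out = {}
    for chrom in signal.values:
        s = signal.values[chrom] * (target / ts)
        i = input_.values[chrom] * (target / ti)
        out[chrom] = (s + pseudocount) / (i + pseudocount)
    return signal.copy_with(out)


def window_means(track: SignalTrack, window: int) -> dict[str, np.ndarray]:
    """Average the binned values into tiling windows of ``window`` bp.

    The trailing partial window averages its available bins.
    """
    if window % track.bin_size != 0 or window < track.bin_size:
        raise ValueError("window must be a positive multiple of bin_size")
    per = window // track.bin_size
    out = {}
    for chrom, v in track.values.items():
        n_win = math.ceil(len(v) / per)
        pad = n_win * per - len(v)
        padded = np.concatenate([v, np.full(pad, np.nan)]) if pad else v
        out[chrom] = np.nanmean(padded.reshape(n_win, per), axis=1)
    return out


def replicate_stats(replicates: Sequence[SignalTrack], window: int) -> WindowStats:
    """Per-window mean and RSD across replicate tracks of one condition.

    RSD uses the sample (n-1) standard deviation divided by the window mean;
    zero-mean windows are flagged undefined.  Three replicates are expected
    but any n >= 2 is accepted (logged).
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates")
    if len(replicates) != 3:
        logger.warning("replicate_stats called with %d replicates (expected 3)",
                       len(replicates))
    g = replicates[0].genome
    for t in replicates[1:]:
        if t.bin_size != replicates[0].bin_size or t.genome.chrom_sizes != g.chrom_sizes:
            raise ValueError("replicates must share genome and bin size")
    wm = [window_means(t, window) for t in replicates]
    mean, rsd, defined = {}, {}, {}
    for chrom in g.chrom_sizes:
        stack = np.vstack([m[chrom] for m in wm])
        mu = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        ok = mu > 0
        r = np.full_like(mu, np.nan)
        r[ok] = sd[ok] / mu[ok]
        mean[chrom], rsd[chrom], defined[chrom] = mu, r, ok
    return WindowStats(g, window, mean, rsd, defined)


def pairwise_correlation(tracks: Sequence[SignalTrack], window: int,
                         means: Optional[Sequence[dict[str, np.ndarray]]] = None,
                         ) -> np.ndarray:
    """Pearson correlation matrix of window-averaged tracks.

    Windows where any track is NaN are dropped listwise.  ``means`` may
    supply precomputed window means (e.g. replicate averages).
    """
    if len(tracks) < 2 and means is None:
        raise ValueError("need >= 2 tracks")
    if means is None:
        means = [window_means(t, window) for t in tracks]
    chroms = list(means[0])
    rows = [np.concatenate([m[c] for c in chroms]) for m in means]
    mat = np.vstack(rows)
    keep = ~np.isnan(mat).any(axis=0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 valid windows for correlation")
    return np.corrcoef(mat[:, keep])


# ---------------------------------------------------------------------------
# bedGraph I/O

def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    """Write the track as bedGraph, run-length compressing equal-value bins."""
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            size = track.genome.chrom_sizes[chrom]
            if len(v) == 0:
                continue
            run_start = 0
            for b in range(1, len(v) + 1):
                if b == len(v) or v[b] != v[run_start]:
                    start = run_start * track.bin_size
                    end = min(b * track.bin_size, size)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v[run_start]:g}\n")
                    run_start = b


def read_bedgraph(path: PathLike, genome: Genome, bin_size: int,
                  meta: Optional[TrackMeta] = None) -> SignalTrack:
    """Read bedGraph into a binned track.

    Each bin's value is the length-weighted mean of the bedGraph records
    covering it (0 where uncovered), so writing and re-reading a track at
    the same bin size round-trips exactly.
    """
    sums = {c: np.zeros(_n_bins(s, bin_size)) for c, s in genome.chrom_sizes.items()}
    cover = {c: np.zeros(_n_bins(s, bin_size)) for c, s in genome.chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            if chrom not in sums:
                continue
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                raise BedParseError(f"{path}:{lineno}: bad record") from None
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: invalid interval")
            end = min(end, genome.chrom_sizes[chrom])
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                sums[chrom][b] += value * (hi - lo)
                cover[chrom][b] += hi - lo
    values = {}
    for chrom in sums:
        v = np.zeros_like(sums[chrom])
        ok = cover[chrom] > 0
        v[ok] = sums[chrom][ok] / cover[chrom][ok]
        values[chrom] = v
    return SignalTrack(genome, bin_size, values,
                       meta if meta is not None else TrackMeta())
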