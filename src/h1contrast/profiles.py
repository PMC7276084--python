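"""Anchor-centered aggregate profiles.

The aggregate profile is the ratio-of-averages: the signal track is
averaged across anchors per offset bin, the Input track likewise, and the
averaged signal is divided by the averaged Input.  Anchors whose flank
would be truncated by a chromosome end are dropped, never zero-padded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import IntervalSet
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

Anchor = tuple[str, int, str]  # chrom, position (bp), strand


@dataclass
class AggregateProfile:
    name: str
    flank: int
    bin: int
    offsets: np.ndarray        # bp, symmetric about 0
    values: np.ndarray         # mean (ratio) per offset bin
    n_anchors: int


def anchor_points(intervals: IntervalSet, mode: str = "center") -> list[Anchor]:
    """Reduce intervals to anchor coordinates.

    center: floor((start+end)/2); start: the start coordinate; five_prime:
    start for '+' (and unstranded), end-1 for '-'.
    """
    out: list[Anchor] = []
    for iv in intervals:
        if mode == "center":
            pos = (iv.start + iv.end) // 2
        elif mode == "start":
            pos = iv.start
        elif mode == "five_prime":
            pos = iv.end - 1 if iv.strand == "-" else iv.start
        else:
            raise ValueError(f"unknown anchor mode {mode!r}")
        out.append((iv.chrom, pos, iv.strand))
    return out


def _offset_bin_map(flank: int, bin: int, bs: int) -> tuple[np.ndarray, np.ndarray]:
    """Map track-resolution offsets to profile offset bins.

    Returns (profile offsets in bp, per-track-bin profile-bin index).
    """
    f = flank // bs
    track_offsets = (np.arange(2 * f + 1) - f) * bs
    k = np.rint(track_offsets / bin).astype(int)
    h = flank // bin
    offsets = np.arange(-h, h + 1) * bin
    return offsets, k + h


def _stack_windows(track: SignalTrack, anchors: Sequence[Anchor], flank: int,
                   strand_aware: bool) -> tuple[np.ndarray, int]:
    """Sum anchor-centered windows at track resolution; returns (sum, n used)."""
    bs = track.bin_size
    f = flank // bs
    total = np.zeros(2 * f + 1)
    used = 0
    for chrom, pos, strand in anchors:
        v = track.values.get(chrom)
        if v is None:
            continue
        c = pos // bs
        if c - f < 0 or c + f >= len(v):
            continue
        win = v[c - f:c + f + 1]
        if strand_aware and strand == "-":
            win = win[::-1]
        total += win
        used += 1
    return total, used


def aggregate_profile(signal: SignalTrack, input_: Optional[SignalTrack],
                      anchors: Sequence[Anchor], flank: int, bin: int,
                      strand_aware: bool = False,
                      name: str = "profile") -> AggregateProfile:
    """Average signal (optionally / average Input) around anchors.

    ``flank`` and ``bin`` must be multiples of the track bin size and
    ``flank`` a multiple of ``bin``.
    """
    bs = signal.bin_size
    if flank % bs or bin % bs or flank % bin:
        raise ValueError("flank and bin must be multiples of the track bin "
                         "size, and flank a multiple of bin")
    if input_ is not None and (input_.bin_size != bs or
                               input_.genome.chrom_sizes != signal.genome.chrom_sizes):
        raise ValueError("signal and input must share genome and bin size")
    sig_sum, n_used = _stack_windows(signal, anchors, flank, strand_aware)
    if n_used == 0:
        raise ValueError("no usable anchors (all truncated or off-genome)")
    offsets, kmap = _offset_bin_map(flank, bin, bs)

    def rebin(arr: np.ndarray) -> np.ndarray:
        out = np.zeros(len(offsets))
        counts = np.zeros(len(offsets))
        np.add.at(out, kmap, arr)
        np.add.at(counts, kmap, 1.0)
        return out / counts

    values = rebin(sig_sum / n_used)
    if input_ is not None:
        inp_sum, n_inp = _stack_windows(input_, anchors, flank, strand_aware)
        if n_inp != n_used:
            raise ValueError("signal and input disagree on usable anchors")
        inp = rebin(inp_sum / n_used)
        if np.any(inp <= 0):
            logger.warning("aggregate_profile(%s): zero Input at %d offset "
                           "bins; ratio set to NaN there", name,
                           int(np.sum(inp <= 0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(inp > 0, values / inp, np.nan)
    return AggregateProfile(name, flank, bin, offsets, values, n_used)


def nucleotide_profile(fasta, anchors: Sequence[Anchor], flank: int,
                       bin: int = 1, name: str = "gc") -> AggregateProfile:
    """Pooled GC fraction per offset bin around anchors.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sequence
    supporting slicing).  N bases are excluded from both numerator and
    denominator; anchors whose flank leaves the chromosome are dropped.
    """
    if flank % bin:
        raise ValueError("flank must be a multiple of bin")
    offsets, kmap = _offset_bin_map(flank, bin, 1)
    gc = np.zeros(len(offsets))
    tot = np.zeros(len(offsets))
    used = dropped = 0
    for chrom, pos, _strand in anchors:
        try:
            record = fasta[chrom]
        except KeyError:
            dropped += 1
            continue
        if pos - flank < 0 or pos + flank + 1 > len(record):
            dropped += 1
            continue
        seq = str(record[pos - flank:pos + flank + 1]).upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_base = is_gc | (arr == ord("A")) | (arr == ord("T"))
        np.add.at(gc, kmap, is_gc.astype(float))
        np.add.at(tot, kmap, is_base.astype(float))
        used += 1
    if dropped:
        logger.info("nucleotide_profile: dropped %d anchors near chromosome "
                    "ends or off-genome", dropped)
    if used == 0:
        raise ValueError("no usable anchors")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(tot > 0, gc / tot, np.nan)
    return AggregateProfile(name, flank, bin, offsets, values, used)


def profile_dip_width(profile: AggregateProfile) -> float:
    """Full width (bp) of a central dip at half depth.

    Baseline is the mean of the outer 10% of offset bins on each side; the
    dip floor is the profile minimum within the central half.  Returns the
    distance between the two crossings of the half-depth level flanking the
    minimum (linear interpolation between bins).
    """
    v = profile.values
    n = len(v)
    edge = max(1, n // 10)
    baseline = float(np.nanmean(np.concatenate([v[:edge], v[-edge:]])))
    mid = slice(n // 4, 3 * n // 4)
    imin = int(np.nanargmin(v[mid])) + n // 4
    depth = baseline - v[imin]
    if depth <= 0:
        raise ValueError("no central dip in profile")
    half = baseline - depth / 2.0
    # walk outwards from the minimum to the half-depth crossings
    left = imin
    while left > 0 and v[left] < half:
        left -= 1
    right = imin
    while right < n - 1 and v[right] < half:
        right += 1
    x = profile.offsets.astype(float)

    def interp(i_out: int, i_in: int) -> float:
        if v[i_out] == v[i_in]:
            return x[i_out]
        t = (half - v[i_in]) / (v[i_out] - v[i_in])
        return x[i_in] + t * (x[i_out] - x[i_in])

    lx = interp(left, left + 1) if v[left] >= half else x[left]
    rx = interp(right, right - 1) if v[right] >= half else x[right]
    return float(rx - lx)
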