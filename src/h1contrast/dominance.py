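"""Detection of genomic regions where one H1 variant dominates the other.

Windows of raw occupancy (default 100 bp) pass the replicate-consistency
filter when each condition's RSD is below ``rsd_max``; a window is assigned
to a variant when the symmetric relative difference of the two condition
means exceeds ``rel_diff_min``.  Consecutive same-label windows merge into
dominant regions, the unit reported against promoters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Genome, GenomicInterval, IntervalSet, count_overlaps
from .tracks import WindowStats

LABEL_NONE, LABEL_A, LABEL_B = 0, 1, 2


@dataclass(frozen=True)
class DominanceParams:
    window: int = 100
    rsd_max: float = 0.5
    rel_diff_min: float = 0.99
    #: "mean" -> |a-b| / ((a+b)/2), range [0, 2] (default);
    #: "max"  -> |a-b| / max(a, b), range [0, 1]
    rel_diff_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.rsd_max <= 0:
            raise ValueError("window and rsd_max must be positive")
        if not 0 < self.rel_diff_min < 2:
            raise ValueError("rel_diff_min must be in (0, 2)")
        if self.rel_diff_mode not in ("mean", "max"):
            raise ValueError("rel_diff_mode must be 'mean' or 'max'")


@dataclass(frozen=True)
class DominantRegion:
    interval: GenomicInterval
    dominant_variant: str
    mean_a: float
    mean_b: float
    max_rsd: float
    n_windows: int


def relative_difference(a: float, b: float, mode: str = "mean") -> float:
    """Symmetric normalized difference between two occupancies.

    Default convention |a-b| / mean(a, b) ranges over [0, 2]; 2.0 means one
    side is zero, and the dominance threshold 0.99 corresponds to roughly a
    3-fold disparity.
    """
    if a < 0 or b < 0:
        raise ValueError("occupancies must be non-negative")
    if a + b == 0:
        raise ValueError("relative difference undefined at a = b = 0")
    if mode == "max":
        return abs(a - b) / max(a, b)
    return abs(a - b) / ((a + b) / 2.0)


def detect_dominant_windows(stats_a: WindowStats, stats_b: WindowStats,
                            params: DominanceParams = DominanceParams(),
                            ) -> dict[str, np.ndarray]:
    """Label each window A, B or none.

    A window is labeled A iff both conditions' RSDs are below ``rsd_max``,
    the relative difference of the window means exceeds ``rel_diff_min``
    and mean_A > mean_B; symmetric for B.  Windows with undefined RSD or
    undefined relative difference get none.
    """
    if stats_a.window != stats_b.window or \
            stats_a.genome.chrom_sizes != stats_b.genome.chrom_sizes:
        raise ValueError("window stats must share genome and window size")
    labels: dict[str, np.ndarray] = {}
    for chrom in stats_a.mean:
        ma, mb = stats_a.mean[chrom], stats_b.mean[chrom]
        ra, rb = stats_a.rsd[chrom], stats_b.rsd[chrom]
        ok = (stats_a.defined[chrom] & stats_b.defined[chrom]
              & (ra < params.rsd_max) & (rb < params.rsd_max))
        tot = ma + mb
        with np.errstate(invalid="ignore", divide="ignore"):
            if params.rel_diff_mode == "max":
                rd = np.abs(ma - mb) / np.maximum(ma, mb)
            else:
                rd = np.abs(ma - mb) / (tot / 2.0)
        ok &= tot > 0
        ok &= rd > params.rel_diff_min
        lab = np.zeros(len(ma), dtype=np.int8)
        lab[ok & (ma > mb)] = LABEL_A
        lab[ok & (mb > ma)] = LABEL_B
        labels[chrom] = lab
    return labels


def merge_dominant_regions(labels: dict[str, np.ndarray], window: int,
                           genome: Genome,
                           stats_a: Optional[WindowStats] = None,
                           stats_b: Optional[WindowStats] = None,
                           variant_a: str = "H1.2",
                           variant_b: str = "H1.5") -> list[DominantRegion]:
    """Run-length encode window labels into dominant regions.

    Maximal runs of consecutive same-label windows become one region; no
    gap bridging.  Region means average the member window means; max_rsd
    is the largest RSD of either condition over member windows.
    """
    regions: list[DominantRegion] = []
    for chrom, lab in labels.items():
        size = genome.chrom_sizes[chrom]
        i = 0
        while i < len(lab):
            if lab[i] == LABEL_NONE:
                i += 1
                continue
            j = i
            while j + 1 < len(lab) and lab[j + 1] == lab[i]:
                j += 1
            start = i * window
            end = min((j + 1) * window, size)
            sl = slice(i, j + 1)
            if stats_a is not None and stats_b is not None:
                mean_a = float(np.mean(stats_a.mean[chrom][sl]))
                mean_b = float(np.mean(stats_b.mean[chrom][sl]))
                max_rsd = float(np.nanmax(
                    np.concatenate([stats_a.rsd[chrom][sl], stats_b.rsd[chrom][sl]])))
            else:
                mean_a = mean_b = max_rsd = float("nan")
            variant = variant_a if lab[i] == LABEL_A else variant_b
            regions.append(DominantRegion(
                GenomicInterval(chrom, start, end), variant,
                mean_a, mean_b, max_rsd, j - i + 1))
            i = j + 1
    return regions


def find_dominant_regions(stats_a: WindowStats, stats_b: WindowStats,
                          genome: Genome,
                          params: DominanceParams = DominanceParams(),
                          variant_a: str = "H1.2",
                          variant_b: str = "H1.5") -> list[DominantRegion]:
    """Convenience: detect windows then merge into regions."""
    labels = detect_dominant_windows(stats_a, stats_b, params)
    return merge_dominant_regions(labels, stats_a.window, genome,
                                  stats_a, stats_b, variant_a, variant_b)


def promoter_overlap_fraction(regions: list[DominantRegion],
                              promoters: IntervalSet) -> float:
    """Fraction of regions overlapping >= 1 promoter interval by >= 1 bp."""
    if not regions:
        raise ValueError("no regions: fraction undefined")
    query = IntervalSet([r.interval for r in regions])
    return count_overlaps(query, promoters) / len(regions)


def regions_to_interval_set(regions: list[DominantRegion],
                            genome: Optional[Genome] = None) -> IntervalSet:
    """Regions as BED-ready intervals (name = variant, score = rel diff x1000)."""
    ivs = []
    for r in regions:
        tot = r.mean_a + r.mean_b
        rd = abs(r.mean_a - r.mean_b) / (tot / 2.0) if tot > 0 else 0.0
        ivs.append(GenomicInterval(r.interval.chrom, r.interval.start,
                                   r.interval.end, score=float(int(rd * 1000)),
                                   name=r.dominant_variant))
    return IntervalSet(ivs, genome=genome, sorted=True)
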