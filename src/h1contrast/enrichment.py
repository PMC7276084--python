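"""Fold enrichment of a peak set within genomic features against a
randomization (shuffle) null.

Fold = observed overlap count / mean overlap count across shuffles, where
the overlap unit is the number of query regions overlapping >= 1 feature
region.  Fold > 1 indicates enrichment over the genomic average, fold < 1
depletion.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Genome, GenomicInterval, IntervalSet, count_overlaps


@dataclass(frozen=True)
class EnrichmentResult:
    query_name: str
    feature_name: str
    observed: int
    expected: float
    fold: Optional[float]
    n_shuffles: int
    #: empirical two-sided tail fraction of the null overlap counts
    p_empirical: float


def shuffle_intervals(s: IntervalSet, genome: Genome,
                      seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None,
                      same_chrom: bool = True) -> IntervalSet:
    """Re-place every interval uniformly at random, preserving its length.

    ``same_chrom`` keeps each interval on its original chromosome; otherwise
    a chromosome is drawn with probability proportional to its size among
    chromosomes long enough to hold the interval.  Placements are
    independent, so shuffled intervals may overlap each other.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = genome.chrom_names
    sizes = np.array([genome.chrom_sizes[c] for c in names], dtype=float)
    out = []
    for iv in s:
        length = len(iv)
        if same_chrom:
            chrom = iv.chrom
            if chrom not in genome:
                raise ValueError(f"interval chromosome {chrom!r} not in genome")
            space = genome.chrom_sizes[chrom] - length
            if space < 0:
                raise ValueError(
                    f"interval of length {length} does not fit on {chrom}")
        else:
            eligible = sizes - length >= 0
            if not eligible.any():
                raise ValueError(
                    f"interval of length {length} fits on no chromosome")
            p = np.where(eligible, sizes, 0.0)
            chrom = names[rng.choice(len(names), p=p / p.sum())]
            space = genome.chrom_sizes[chrom] - length
        start = int(rng.integers(0, space + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out, genome=genome)


def fold_enrichment(query: IntervalSet, feature: IntervalSet, genome: Genome,
                    n_shuffles: int = 1000, seed: Optional[int] = None,
                    same_chrom: bool = True,
                    query_name: str = "query",
                    feature_name: str = "feature") -> EnrichmentResult:
    """Observed / shuffle-expected overlap count of query regions in features."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(query) == 0 or len(feature) == 0:
        raise ValueError("empty query or feature set: fold undefined")
    observed = count_overlaps(query, feature)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = shuffle_intervals(query, genome, rng=rng, same_chrom=same_chrom)
        null[i] = count_overlaps(shuf, feature)
    expected = float(null.mean())
    fold = observed / expected if expected > 0 else None
    lo = float(np.mean(null <= observed))
    hi = float(np.mean(null >= observed))
    p = min(1.0, 2.0 * min(lo, hi))
    return EnrichmentResult(query_name, feature_name, observed, expected,
                            fold, n_shuffles, p)
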