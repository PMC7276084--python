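"""DNA-methylation profiles around nucleosome dyads, CpGs and peak centers.

Per-CpG methylation tables (chrom, position, methylated fraction, read
coverage) are profiled around anchor points with coverage weighting — the
variance-optimal convention for bisulfite fractions.  Nucleosome dyads are
stratified by CpG-island membership and by which H1 ChIP signal's peaks
they fall in, giving the 2 x 4 anchor classes compared downstream.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Genome, IntervalSet, PathLike, merge_intervals
from .profiles import Anchor, AggregateProfile, aggregate_profile
from .tracks import SignalTrack

METH_COLUMNS = ("chrom", "pos", "fraction", "coverage")


@dataclass
class MethylationTable:
    """Per-chromosome sorted CpG positions with methylation fraction and coverage."""

    pos: dict[str, np.ndarray]
    fraction: dict[str, np.ndarray]
    coverage: dict[str, np.ndarray]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MethylationTable":
        if not set(METH_COLUMNS) <= set(df.columns):
            raise ValueError(f"methylation table needs columns {METH_COLUMNS}")
        if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
            raise ValueError("methylation fractions must lie in [0, 1]")
        if (df["coverage"] < 1).any():
            raise ValueError("coverage must be >= 1")
        pos, frac, cov = {}, {}, {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            p = sub["pos"].to_numpy(dtype=np.int64)
            if len(np.unique(p)) != len(p):
                raise ValueError(f"duplicate CpG positions on {chrom}")
            pos[chrom] = p
            frac[chrom] = sub["fraction"].to_numpy(dtype=float)
            cov[chrom] = sub["coverage"].to_numpy(dtype=np.int64)
        return cls(pos, frac, cov)

    def to_dataframe(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": chrom, "pos": self.pos[chrom],
                                "fraction": self.fraction[chrom],
                                "coverage": self.coverage[chrom]})
                  for chrom in self.pos]
        return pd.concat(frames, ignore_index=True)

    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.pos.values()))


def read_methylation_table(path: PathLike) -> MethylationTable:
    df = pd.read_csv(path, sep="\t", names=list(METH_COLUMNS), comment="#")
    return MethylationTable.from_dataframe(df)


def write_methylation_table(table: MethylationTable, path: PathLike) -> None:
    table.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


@dataclass
class AnchorClass:
    inside_cpg_island: bool
    h1_signal: str
    anchors: list[Anchor]


def _point_membership(intervals: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals)
    out = {}
    for chrom, ivs in merged.by_chrom().items():
        out[chrom] = (np.array([iv.start for iv in ivs]),
                      np.array([iv.end for iv in ivs]))
    return out


def _inside(lookup: dict[str, tuple[np.ndarray, np.ndarray]],
            chrom: str, pos: int) -> bool:
    se = lookup.get(chrom)
    if se is None:
        return False
    starts, ends = se
    idx = np.searchsorted(starts, pos, side="right")
    return idx > 0 and ends[idx - 1] > pos


def classify_nucleosomes(dyads: IntervalSet, cpg_islands: IntervalSet,
                         h1_peak_sets: dict[str, IntervalSet],
                         ) -> list[AnchorClass]:
    """Partition nucleosome dyads into (island flag) x (H1 signal) classes.

    A dyad enters class (flag, signal) iff its center lies inside a CpG
    island (flag) and inside a peak of that signal; dyads in no peak are
    dropped.  A dyad may appear in several signal classes but exactly one
    island class.
    """
    island_lookup = _point_membership(cpg_islands)
    peak_lookups = {name: _point_membership(s) for name, s in h1_peak_sets.items()}
    classes = {(flag, name): AnchorClass(flag, name, [])
               for flag in (True, False) for name in h1_peak_sets}
    for iv in dyads:
        pos = iv.center
        flag = _inside(island_lookup, iv.chrom, pos)
        for name, lookup in peak_lookups.items():
            if _inside(lookup, iv.chrom, pos):
                classes[(flag, name)].anchors.append((iv.chrom, pos, iv.strand))
    return list(classes.values())


def methylation_profile(meth: MethylationTable, anchors: Sequence[Anchor],
                        flank: int, bin: int = 10,
                        min_coverage: int = 5) -> AggregateProfile:
    """Coverage-weighted mean methylation per offset bin around anchors.

    CpGs under ``min_coverage`` reads are ignored; offset bins with no CpG
    are NaN.  Offsets run -flank..+flank in steps of ``bin`` (CpG assigned
    to the nearest offset bin center).
    """
    if not anchors:
        raise ValueError("no anchors")
    if flank % bin:
        raise ValueError("flank must be a multiple of bin")
    h = flank // bin
    n_off = 2 * h + 1
    wsum = np.zeros(n_off)
    w = np.zeros(n_off)
    for chrom, pos, _strand in anchors:
        p = meth.pos.get(chrom)
        if p is None:
            continue
        lo = np.searchsorted(p, pos - flank, side="left")
        hi = np.searchsorted(p, pos + flank, side="right")
        if hi <= lo:
            continue
        cov = meth.coverage[chrom][lo:hi]
        frac = meth.fraction[chrom][lo:hi]
        keep = cov >= min_coverage
        if not keep.any():
            continue
        k = np.rint((p[lo:hi][keep] - pos) / bin).astype(int) + h
        ok = (k >= 0) & (k < n_off)
        np.add.at(wsum, k[ok], frac[keep][ok] * cov[keep][ok])
        np.add.at(w, k[ok], cov[keep][ok])
    if not (w > 0).any():
        raise ValueError("all offset bins undefined: no covered CpGs near anchors")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(w > 0, wsum / w, np.nan)
    offsets = (np.arange(n_off) - h) * bin
    return AggregateProfile("methylation", flank, bin, offsets, values,
                            len(anchors))


def signal_profile_around_points(signal: SignalTrack,
                                 points: Sequence[Anchor], flank: int,
                                 bin: int,
                                 input_: Optional[SignalTrack] = None,
                                 name: str = "profile") -> AggregateProfile:
    """Aggregate signal profile around unstranded point anchors (CpGs, peak
    centers); thin wrapper over :func:`aggregate_profile`."""
    if not points:
        raise ValueError("no points")
    anchors = [(c, p, ".") for c, p, *_ in points]
    return aggregate_profile(signal, input_, anchors, flank, bin,
                             strand_aware=False, name=name)
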