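"""Core genomic domain types, interval algebra and text-format I/O.

Coordinates are 0-based half-open throughout (BED convention).  Chromosome
order is the order of the chromosome-size table (assembly order), never
lexicographic, so toy genomes and real assemblies sort the same way.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed BED/bedGraph record; message names the offending line."""


@dataclass(frozen=True)
class Genome:
    """An assembly: ordered chromosome names and their lengths in bp."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive size {size}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)

    def rank(self, chrom: str) -> int:
        """Sort rank of a chromosome (table order)."""
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class GenomicInterval:
    """One region: 0-based half-open [start, end) with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap by >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Collection of genomic intervals, sortable by (chrom rank, start, end)."""

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[Genome] = None,
        sorted: bool = False,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome = genome
        self.is_sorted = sorted
        if genome is not None:
            for iv in self.intervals:
                if iv.chrom in genome and iv.end > genome.chrom_sizes[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome size {genome.chrom_sizes[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def _chrom_rank(self, chrom: str) -> tuple:
        if self.genome is not None and chrom in self.genome:
            return (0, self.genome.rank(chrom))
        # fallback for genome-less sets: name order, stable and deterministic
        return (1, chrom)

    def sort(self) -> "IntervalSet":
        """Return a new set sorted by (chrom rank, start, end)."""
        ivs = sorted(
            self.intervals, key=lambda iv: (self._chrom_rank(iv.chrom), iv.start, iv.end)
        )
        return IntervalSet(ivs, genome=self.genome, sorted=True)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.sort() if not self.is_sorted else self:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def merge_intervals(s: IntervalSet) -> IntervalSet:
    """Minimal disjoint cover of the same bases; bookended runs are merged.

    Strand is ignored; merged intervals are unstranded.
    """
    merged: list[GenomicInterval] = []
    for chrom, ivs in s.by_chrom().items():
        cur_start, cur_end = None, None
        for iv in ivs:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:  # touching counts as overlapping
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged, genome=s.genome, sorted=True)


def count_overlaps(query: IntervalSet, feature: IntervalSet) -> int:
    """Number of query intervals overlapping >= 1 feature interval by >= 1 bp.

    Strand-blind, bedtools-intersect semantics (any shared base counts).
    """
    merged = merge_intervals(feature)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in merged.by_chrom().items():
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])
    n = 0
    for iv in query:
        if iv.chrom not in starts:
            continue
        fs, fe = starts[iv.chrom], ends[iv.chrom]
        # merged intervals are disjoint+sorted: the only candidate is the
        # last feature starting before the query end
        idx = np.searchsorted(fs, iv.end, side="left")
        if idx > 0 and fe[idx - 1] > iv.start:
            n += 1
    return n


# ---------------------------------------------------------------------------
# text I/O

def read_chrom_sizes(path: PathLike) -> Genome:
    """Read a two-column (name, length) chromosome-size table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer size {parts[1]!r}"
                ) from None
    return Genome(sizes)


def write_chrom_sizes(genome: Genome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, size in genome.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(path: PathLike, genome: Optional[Genome] = None) -> IntervalSet:
    """Read BED3/BED6 into a sorted IntervalSet.

    Records on chromosomes absent from ``genome`` (when given) are dropped
    and the count logged.  Malformed lines raise :class:`BedParseError`
    naming the line number.
    """
    ivs: list[GenomicInterval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            if genome is not None and chrom not in genome:
                dropped += 1
                continue
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            ivs.append(GenomicInterval(chrom, start, end, strand, score, name))
    if dropped:
        logger.info("read_bed(%s): dropped %d records on unknown chromosomes",
                    path, dropped)
    return IntervalSet(ivs, genome=genome).sort()


def write_bed(s: IntervalSet, path: PathLike) -> None:
    """Write BED; emits BED6 when any record carries strand/score/name."""
    bed6 = any(iv.strand != "." or iv.score is not None or iv.name is not None
               for iv in s)
    with open(path, "w") as fh:
        for iv in s:
            if bed6:
                score = "0" if iv.score is None else format(iv.score, "g")
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
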