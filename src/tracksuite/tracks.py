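"""Interval representation of genomic tracks and exact bp-level set operations.

Coordinates are 0-based, half-open (BED convention) throughout.  A track is a
per-chromosome, sorted, *merged* set of segments: after normalization no two
segments on a chromosome overlap or touch.  Points are 1 bp segments, so one
code path serves point and segment tracks alike.  Strand is ignored — every
statistic in this package is defined on covered base pairs only.

Intervals outside chromosome bounds are errors, never clipped: silent clipping
hides genome-version mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .genome import GenomeDefinition, GenomeMismatchError


class Segment(NamedTuple):
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class BedFormatError(ValueError):
    """Raised for malformed or out-of-bounds BED input."""


@dataclass(frozen=True)
class ContingencyTable:
    """Base-pair counts (both / only-A / only-B / neither), summing to N.

    Each base pair of the genome is one observation; the table is the input
    to every pairwise co-occurrence statistic.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for cell in (self.n_both, self.n_a_only, self.n_b_only, self.n_neither):
            if cell < 0:
                raise ValueError(f"negative contingency cell: {self}")

    @property
    def N(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def coverage_a(self) -> int:
        return self.n_both + self.n_a_only

    @property
    def coverage_b(self) -> int:
        return self.n_both + self.n_b_only

    def swapped(self) -> "ContingencyTable":
        return ContingencyTable(self.n_both, self.n_b_only, self.n_a_only,
                                self.n_neither)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_both, self.n_a_only, self.n_b_only, self.n_neither)


def merge_intervals(starts: np.ndarray, ends: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if len(starts) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    # running maximum of ends; a new block starts where start > max end so far
    running_end = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > running_end[:-1]
    idx = np.flatnonzero(new_block)
    merged_starts = s[idx]
    block_end_idx = np.append(idx[1:], len(s)) - 1
    merged_ends = running_end[block_end_idx]
    return merged_starts, merged_ends


def _intersect_bp_arrays(s1: np.ndarray, e1: np.ndarray,
                         s2: np.ndarray, e2: np.ndarray) -> int:
    """Overlap bp between two merged, sorted interval sets."""
    if len(s1) == 0 or len(s2) == 0:
        return 0
    cum = np.concatenate(([0], np.cumsum(e2 - s2)))
    lo = np.searchsorted(e2, s1, side="right")
    hi = np.searchsorted(s2, e1, side="left")
    valid = hi > lo
    if not valid.any():
        return 0
    lov, hiv = lo[valid], hi[valid]
    contrib = cum[hiv] - cum[lov]
    # only the first/last overlapped interval can protrude past the query
    left_clip = np.maximum(0, s1[valid] - s2[lov])
    right_clip = np.maximum(0, e2[hiv - 1] - e1[valid])
    return int(np.sum(contrib - left_clip - right_clip))


class Track:
    """A normalized genomic track: per-chromosome sorted, merged segments.

    Construct via :meth:`from_segments` or :func:`read_bed`; the constructor
    assumes already-normalized arrays.
    """

    def __init__(self, genome: GenomeDefinition,
                 by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
                 label: str = "",
                 elements_pre_merge: int | None = None) -> None:
        self.genome = genome
        self._by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in by_chrom.items() if len(s)
        }
        self.label = label
        self.elements_pre_merge = (
            elements_pre_merge if elements_pre_merge is not None
            else self.segment_count
        )

    @classmethod
    def from_segments(cls, genome: GenomeDefinition,
                      segments: Iterable[tuple[str, int, int] | Segment],
                      label: str = "") -> "Track":
        """Validate, sort and merge raw segments into a normalized Track."""
        raw: dict[str, list[tuple[int, int]]] = {}
        count = 0
        for seg in segments:
            chrom, start, end = seg[0], int(seg[1]), int(seg[2])
            if chrom not in genome:
                raise BedFormatError(
                    f"unknown chromosome {chrom!r} for genome {genome.name!r}"
                )
            if start >= end:
                raise BedFormatError(
                    f"empty or inverted interval {chrom}:{start}-{end}"
                )
            if start < 0 or end > genome.length_of(chrom):
                raise BedFormatError(
                    f"interval {chrom}:{start}-{end} exceeds chromosome "
                    f"bounds [0, {genome.length_of(chrom)})"
                )
            raw.setdefault(chrom, []).append((start, end))
            count += 1
        by_chrom = {}
        for chrom, pairs in raw.items():
            arr = np.asarray(pairs, dtype=np.int64)
            by_chrom[chrom] = merge_intervals(arr[:, 0], arr[:, 1])
        return cls(genome, by_chrom, label=label, elements_pre_merge=count)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) on a chromosome; empty arrays if uncovered."""
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty))

    @property
    def coverage_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self._by_chrom.values()))

    @property
    def segment_count(self) -> int:
        return int(sum(len(s) for s, _ in self._by_chrom.values()))

    @property
    def is_empty(self) -> bool:
        return self.segment_count == 0

    def segments(self) -> Iterator[Segment]:
        """Segments in genome chromosome order."""
        for chrom, _ in self.genome:
            s, e = self.arrays(chrom)
            for i in range(len(s)):
                yield Segment(chrom, int(s[i]), int(e[i]))

    def coverage_fraction(self) -> float:
        return self.coverage_bp / self.genome.N

    def with_label(self, label: str) -> "Track":
        return Track(self.genome, self._by_chrom, label=label,
                     elements_pre_merge=self.elements_pre_merge)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        if self.genome != other.genome:
            return False
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c][0], other._by_chrom[c][0])
            and np.array_equal(self._by_chrom[c][1], other._by_chrom[c][1])
            for c in self._by_chrom
        )

    def __repr__(self) -> str:
        return (f"Track({self.label or '<unlabeled>'}, "
                f"{self.segment_count} segments, {self.coverage_bp} bp)")


def _check_same_genome(a: Track, b: Track) -> None:
    if a.genome != b.genome:
        raise GenomeMismatchError(
            f"tracks are on different genomes "
            f"({a.genome.name!r} vs {b.genome.name!r})"
        )


def read_bed(path: str | Path, genome: GenomeDefinition,
             label: str | None = None) -> Track:
    """Read a BED3+ file into a normalized Track.

    Only the first three columns are interpreted.  ``track``/``browser`` and
    ``#`` comment lines are skipped.  Out-of-bounds intervals, unknown
    chromosomes and empty intervals are errors.
    """
    path = Path(path)
    segs: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise BedFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedFormatError(
                f"{path}:{lineno}: non-integer coordinates"
            ) from None
        segs.append((fields[0], start, end))
    try:
        return Track.from_segments(
            genome, segs, label=label if label is not None else path.stem
        )
    except BedFormatError as err:
        raise BedFormatError(f"{path}: {err}") from None


def write_bed(track: Track, path: str | Path) -> None:
    """Write a Track as BED3 in genome chromosome order (round-trip exact)."""
    with open(path, "w") as fh:
        for seg in track.segments():
            fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\n")


def intersect_bp(a: Track, b: Track) -> int:
    """Exact count of base pairs covered by both tracks."""
    _check_same_genome(a, b)
    total = 0
    for chrom in a._by_chrom:
        s2, e2 = b.arrays(chrom)
        if len(s2):
            s1, e1 = a.arrays(chrom)
            total += _intersect_bp_arrays(s1, e1, s2, e2)
    return total


def contingency_table(a: Track, b: Track) -> ContingencyTable:
    """bp-level 2x2 table over the whole genome (cells sum to N)."""
    _check_same_genome(a, b)
    both = intersect_bp(a, b)
    cov_a, cov_b = a.coverage_bp, b.coverage_bp
    return ContingencyTable(
        n_both=both,
        n_a_only=cov_a - both,
        n_b_only=cov_b - both,
        n_neither=a.genome.N - cov_a - cov_b + both,
    )


def clip_to_segment(track: Track, seg: Segment
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Track intervals clipped to one segment (merged, sorted arrays)."""
    s, e = track.arrays(seg.chromosome)
    if not len(s):
        return s, e
    lo = np.searchsorted(e, seg.start, side="right")
    hi = np.searchsorted(s, seg.end, side="left")
    cs = np.clip(s[lo:hi], seg.start, seg.end)
    ce = np.clip(e[lo:hi], seg.start, seg.end)
    return cs, ce


def coverage_in_bin(track: Track, bin: Segment) -> int:
    """bp of track within one bin."""
    if bin.chromosome not in track.genome:
        raise KeyError(f"bin chromosome {bin.chromosome!r} not in genome")
    if bin.start < 0 or bin.end > track.genome.length_of(bin.chromosome):
        raise ValueError(f"bin {bin} exceeds chromosome bounds")
    cs, ce = clip_to_segment(track, bin)
    return int((ce - cs).sum())


def contingency_in_bin(a: Track, b: Track, bin: Segment) -> ContingencyTable:
    """bp-level 2x2 table using the bin as the universe (N -> bin length)."""
    _check_same_genome(a, b)
    s1, e1 = clip_to_segment(a, bin)
    s2, e2 = clip_to_segment(b, bin)
    both = _intersect_bp_arrays(s1, e1, s2, e2)
    cov_a = int((e1 - s1).sum())
    cov_b = int((e2 - s2).sum())
    return ContingencyTable(
        n_both=both,
        n_a_only=cov_a - both,
        n_b_only=cov_b - both,
        n_neither=bin.length - cov_a - cov_b + both,
    )


@dataclass(frozen=True)
class BinSpec:
    """An ordered list of named genome regions used as aggregation units."""

    bins: tuple[tuple[str, Segment], ...]
    source: str = "user-supplied"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.bins]
        if len(set(names)) != len(names):
            raise ValueError("bin names must be unique")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self) -> Iterator[tuple[str, Segment]]:
        return iter(self.bins)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.bins)

    @property
    def total_bp(self) -> int:
        return sum(seg.length for _, seg in self.bins)


def make_bins(genome: GenomeDefinition, width: int) -> BinSpec:
    """Fixed-width bins tiling each chromosome; last bin may be shorter."""
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    bins: list[tuple[str, Segment]] = []
    for chrom, length in genome:
        for start in range(0, length, width):
            end = min(start + width, length)
            bins.append((f"{chrom}:{start}-{end}", Segment(chrom, start, end)))
    return BinSpec(bins=tuple(bins), source="fixed-width")


def bins_from_track(track: Track) -> BinSpec:
    """Use the segments of a (bed-derived) track as named bins."""
    bins = tuple(
        (f"{seg.chromosome}:{seg.start}-{seg.end}", seg)
        for seg in track.segments()
    )
    if not bins:
        raise ValueError("bin track is empty")
    return BinSpec(bins=bins, source="user-supplied")
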