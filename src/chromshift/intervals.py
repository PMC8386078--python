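"""Genomic interval primitives.

All coordinates in this package are 0-based half-open (BED convention):
an interval covers positions ``start .. end-1`` and its length is
``end - start``. A single helper, :func:`to_one_based`, converts to the
1-based inclusive coordinates used for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Deterministic integer center: floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Summit:
    """A single-bp point of maximal signal inside a parent region."""

    chrom: str
    pos: int
    source_region: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.source_region is not None and not self.source_region.contains(
            self.chrom, self.pos
        ):
            raise ValueError(
                f"summit {self.chrom}:{self.pos} outside parent region "
                f"{self.source_region.chrom}:{self.source_region.start}-"
                f"{self.source_region.end}"
            )


def to_one_based(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert to 1-based inclusive (display) coordinates."""
    return interval.chrom, interval.start + 1, interval.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or book-ended intervals are merged.

    Output is sorted by (chrom, start) and strand-agnostic (merged
    intervals carry strand '.').
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


class IntervalIndex:
    """Sorted-array index over a fixed interval collection.

    Supports 1-bp-overlap queries and nearest-point lookups via binary
    search. Intervals may overlap each other.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx_arr = np.asarray(idx)
            starts = np.array([self.intervals[i].start for i in idx])
            ends = np.array([self.intervals[i].end for i in idx])
            order = np.argsort(starts, kind="stable")
            starts, ends, idx_arr = starts[order], ends[order], idx_arr[order]
            # running max of ends lets us bound the left scan for overlap
            max_ends = np.maximum.accumulate(ends)
            self._chrom[chrom] = (starts, ends, idx_arr)
            by_chrom[chrom] = max_ends  # type: ignore[assignment]
        self._max_ends = {c: by_chrom[c] for c in self._chrom}

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into the original collection) overlapping by >= 1 bp."""
        if query.chrom not in self._chrom:
            return []
        starts, ends, idx = self._chrom[query.chrom]
        max_ends = self._max_ends[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        # scan left while any interval could still reach the query start
        lo = int(np.searchsorted(max_ends[:hi], query.start, side="right"))
        hits = [
            int(idx[j])
            for j in range(lo, hi)
            if ends[j] > query.start and starts[j] < query.end
        ]
        return hits

    def containing_point(self, chrom: str, pos: int) -> list[int]:
        return self.overlapping(GenomicInterval(chrom, pos, pos + 1))


def nearest_point_distance(
    query_chrom: str, query_pos: int, points_by_chrom: dict[str, np.ndarray]
) -> float:
    """Distance from a point to the nearest point on the same chromosome.

    Returns ``nan`` when the chromosome holds no points. ``points_by_chrom``
    values must be sorted ascending.
    """
    pts = points_by_chrom.get(query_chrom)
    if pts is None or len(pts) == 0:
        return float("nan")
    j = int(np.searchsorted(pts, query_pos))
    cands = []
    if j > 0:
        cands.append(abs(query_pos - int(pts[j - 1])))
    if j < len(pts):
        cands.append(abs(query_pos - int(pts[j])))
    return float(min(cands))
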