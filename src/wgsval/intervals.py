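"""Genomic interval sets with BED semantics.

All intervals are 0-based, half-open ``[start, end)`` on a single named
sequence, matching the BED convention.  Variant coordinates elsewhere in the
package are VCF-style 1-based; conversion between the two happens only at the
I/O boundary (:mod:`wgsval.io`) and in :meth:`IntervalSet.contains_position`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["Interval", "IntervalSet"]


@dataclass(frozen=True, order=True)
class Interval:
    """One half-open genomic interval with an optional annotation label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of labeled half-open intervals.

    Set-algebra operations (union, intersection, subtraction) treat the
    collection as the set of covered bases and return merged, sorted results
    with labels dropped; label-preserving access goes through
    :attr:`intervals`.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):  # noqa: D107
        self.intervals: list[Interval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple], chrom: str | None = None
    ) -> "IntervalSet":
        """Build from ``(start, end)``, ``(chrom, start, end)`` or
        ``(chrom, start, end, label)`` tuples."""
        out = []
        for t in tuples:
            if len(t) == 2:
                if chrom is None:
                    raise ValueError("chrom required for (start, end) tuples")
                out.append(Interval(chrom, int(t[0]), int(t[1])))
            elif len(t) == 3:
                out.append(Interval(str(t[0]), int(t[1]), int(t[2])))
            else:
                out.append(Interval(str(t[0]), int(t[1]), int(t[2]), str(t[3])))
        return cls(out)

    # -- basic protocol ----------------------------------------------------
    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"IntervalSet({self.intervals!r})"

    @property
    def chroms(self) -> list[str]:
        seen = dict.fromkeys(iv.chrom for iv in self.intervals)
        return list(seen)

    def total_bases(self) -> int:
        """Number of covered bases, counting overlapping intervals once."""
        return sum(len(iv) for iv in self.merge())

    # -- algebra -----------------------------------------------------------
    def merge(self) -> "IntervalSet":
        """Merge touching or overlapping intervals (labels dropped)."""
        merged: list[Interval] = []
        for iv in self.intervals:
            if (
                merged
                and merged[-1].chrom == iv.chrom
                and iv.start <= merged[-1].end
            ):
                if iv.end > merged[-1].end:
                    merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
            else:
                merged.append(Interval(iv.chrom, iv.start, iv.end))
        return IntervalSet(merged)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet([*self.intervals, *other.intervals]).merge()

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        a, b = self.merge().intervals, other.merge().intervals
        out: list[Interval] = []
        i = j = 0
        while i < len(a) and j < len(b):
            x, y = a[i], b[j]
            if x.chrom != y.chrom:
                if (x.chrom, x.start) < (y.chrom, y.start):
                    i += 1
                else:
                    j += 1
                continue
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if lo < hi:
                out.append(Interval(x.chrom, lo, hi))
            if x.end <= y.end:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in ``self`` not covered by ``other``."""
        result: list[Interval] = []
        by_chrom: dict[str, list[Interval]] = {}
        for iv in other.merge():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for iv in self.merge():
            cur = iv.start
            for sub in by_chrom.get(iv.chrom, []):
                if sub.end <= cur or sub.start >= iv.end:
                    continue
                if sub.start > cur:
                    result.append(Interval(iv.chrom, cur, sub.start))
                cur = max(cur, sub.end)
                if cur >= iv.end:
                    break
            if cur < iv.end:
                result.append(Interval(iv.chrom, cur, iv.end))
        return IntervalSet(result)

    # -- queries -----------------------------------------------------------
    def contains(self, chrom: str, pos0: int) -> bool:
        """Whether 0-based position ``pos0`` is covered."""
        return any(
            iv.chrom == chrom and iv.start <= pos0 < iv.end for iv in self.intervals
        )

    def contains_position(self, chrom: str, pos1: int) -> bool:
        """Whether VCF-style 1-based position ``pos1`` is covered."""
        return self.contains(chrom, pos1 - 1)

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        """Whether the 0-based half-open span ``[start, end)`` overlaps."""
        return any(
            iv.chrom == chrom and iv.start < end and start < iv.end
            for iv in self.intervals
        )

    def covered_positions(self, chrom: str | None = None) -> np.ndarray:
        """All covered 0-based positions, for small oracle-style checks."""
        pieces = [
            np.arange(iv.start, iv.end)
            for iv in self.merge()
            if chrom is None or iv.chrom == chrom
        ]
        if not pieces:
            return np.empty(0, dtype=int)
        return np.concatenate(pieces)

    def relabel(self, label: str) -> "IntervalSet":
        return IntervalSet(
            [Interval(iv.chrom, iv.start, iv.end, label) for iv in self.intervals]
        )
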