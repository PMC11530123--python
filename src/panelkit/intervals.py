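"""Genomic interval primitives.

All coordinates are 0-based, half-open. BED files map onto this convention
directly; 1-based sources (VCF positions) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            self.name,
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, merging pairs separated by at most ``gap`` bases.

    Returns intervals sorted by (chrom, start); names are dropped.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def subtract_intervals(
    intervals: Sequence[GenomicInterval], others: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference ``intervals \\ others``, both treated as base sets."""
    cutters = merge_intervals(others)
    out: list[GenomicInterval] = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for cut in cutters:
            if cut.chrom != iv.chrom:
                continue
            next_pieces = []
            for s, e in pieces:
                if cut.end <= s or cut.start >= e:
                    next_pieces.append((s, e))
                    continue
                if s < cut.start:
                    next_pieces.append((s, cut.start))
                if cut.end < e:
                    next_pieces.append((cut.end, e))
            pieces = next_pieces
        out.extend(GenomicInterval(iv.chrom, s, e, iv.name) for s, e in pieces)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    ov = a.intersection_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)
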