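"""Alignment record model, read filters and per-base coverage primitives.

``AlignmentRecord.span`` is the reference-advancing footprint of the
alignment (match/mismatch/deletion); soft-clipped read bases are excluded so
that coverage is well defined.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pysam

from .intervals import GenomicInterval

DEFAULT_MIN_MAPQ = 50

_CHANNEL_SUFFIX = re.compile(r"_ch(\d+)$")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chrom: Optional[str]
    span: Optional[GenomicInterval]
    mapq: int
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False
    channel: Optional[int] = None
    start_time: Optional[float] = None  # seconds since run start
    haplotype: Optional[int] = None  # HP tag
    phase_set: Optional[int] = None  # PS tag

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.is_unmapped and self.span is not None:
            raise ValueError("unmapped records carry no span")
        if not self.is_unmapped and self.span is None:
            raise ValueError("mapped records require a span")

    @property
    def is_primary(self) -> bool:
        return not (
            self.is_unmapped
            or self.is_secondary
            or self.is_supplementary
            or self.is_duplicate
        )


@dataclass
class CoverageProfile:
    interval: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.depth) != self.interval.length:
            raise ValueError("depth array length must equal interval length")

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


def filter_primary(
    records: Iterable[AlignmentRecord], min_mapq: int = DEFAULT_MIN_MAPQ
) -> list[AlignmentRecord]:
    """Keep mapped primary, non-duplicate records with mapq >= ``min_mapq``."""
    return [r for r in records if r.is_primary and r.mapq >= min_mapq]


def overlap_bases(record: AlignmentRecord, interval: GenomicInterval) -> int:
    """Number of reference bases of ``record`` falling inside ``interval``."""
    if record.span is None:
        return 0
    return record.span.intersection_length(interval)


def depth_profile(
    records: Iterable[AlignmentRecord], interval: GenomicInterval
) -> CoverageProfile:
    depth = np.zeros(interval.length, dtype=np.int64)
    for rec in records:
        if rec.span is None or rec.span.chrom != interval.chrom:
            continue
        s = max(rec.span.start, interval.start) - interval.start
        e = min(rec.span.end, interval.end) - interval.start
        if e > s:
            depth[s:e] += 1
    return CoverageProfile(interval=interval, depth=depth)


def _channel_of(seg: pysam.AlignedSegment) -> Optional[int]:
    if seg.has_tag("ch"):
        return int(seg.get_tag("ch"))
    m = _CHANNEL_SUFFIX.search(seg.query_name or "")
    return int(m.group(1)) if m else None


def record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    if seg.is_unmapped:
        span = None
        chrom = None
    else:
        chrom = seg.reference_name
        span = GenomicInterval(chrom, seg.reference_start, seg.reference_end)
    return AlignmentRecord(
        read_id=seg.query_name,
        chrom=chrom,
        span=span,
        mapq=seg.mapping_quality,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
        is_duplicate=seg.is_duplicate,
        is_unmapped=seg.is_unmapped,
        channel=_channel_of(seg),
        start_time=float(seg.get_tag("st")) if seg.has_tag("st") else None,
        haplotype=int(seg.get_tag("HP")) if seg.has_tag("HP") else None,
        phase_set=int(seg.get_tag("PS")) if seg.has_tag("PS") else None,
    )


def read_alignments(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Load SAM/BAM alignments into records; tags tolerated as absent."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [record_from_pysam(seg) for seg in fh]
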