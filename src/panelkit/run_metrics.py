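"""Run-level statistics: channel-partitioned enrichment, per-locus coverage,
phase breadth over strict gene boundaries, and time-to-phase.

Enrichment is the unweighted mean per-locus target coverage from the
adaptive-sampling channels divided by genome background coverage estimated
from non-overlapping windows (default 10 kb) on the nonadaptive channels,
with any window touching a target excluded.
"""

from __future__ import annotations

import os
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .alignment_core import AlignmentRecord, overlap_bases
from .intervals import GenomicInterval, merge_intervals, total_length

DEFAULT_WINDOW = 10_000


@dataclass(frozen=True)
class ChannelPartition:
    adaptive_channels: frozenset[int]
    nonadaptive_channels: frozenset[int]

    def __post_init__(self) -> None:
        if self.adaptive_channels & self.nonadaptive_channels:
            raise ValueError("adaptive and nonadaptive channel sets must be disjoint")


@dataclass
class TargetCoverage:
    mean: float
    per_locus: dict[str, float]


@dataclass
class BackgroundCoverage:
    mean: float
    n_windows: int


@dataclass
class EnrichmentResult:
    mean_target_coverage: float
    background_coverage: float
    enrichment: Optional[float]  # None when background is zero
    n_windows: int


@dataclass(frozen=True)
class PhaseBlock:
    chrom: str
    interval: GenomicInterval
    phase_set: int


@dataclass
class PhaseBreadthRow:
    name: str
    core_length: int
    phased_bases: int
    breadth: float
    fully_phased: bool


@dataclass
class PhaseBreadthResult:
    rows: list[PhaseBreadthRow]

    def row(self, name: str) -> PhaseBreadthRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def summary(self, full_phase_tolerance: float = 0.0) -> dict[str, float]:
        vals = [r.breadth for r in self.rows]
        if not vals:
            return {}
        q = statistics.quantiles(vals, n=4) if len(vals) >= 2 else [vals[0]] * 3
        return {
            "mean": statistics.fmean(vals),
            "median": statistics.median(vals),
            "q1": q[0],
            "q3": q[2],
            "fraction_fully_phased": sum(
                1 for v in vals if v >= 1.0 - full_phase_tolerance
            )
            / len(vals),
        }


@dataclass
class TimeToPhase:
    seconds: Optional[float]  # None = never satisfied
    n_without_timestamp: int = 0


def partition_channels(
    records: Iterable[AlignmentRecord], partition: ChannelPartition
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], int]:
    """Route records by channel id; channel-less records count as unassigned."""
    adaptive, nonadaptive, unassigned = [], [], 0
    for rec in records:
        if rec.channel in partition.adaptive_channels:
            adaptive.append(rec)
        elif rec.channel in partition.nonadaptive_channels:
            nonadaptive.append(rec)
        else:
            unassigned += 1
    return adaptive, nonadaptive, unassigned


def mean_target_coverage(records: Iterable[AlignmentRecord], panel) -> TargetCoverage:
    """Per-locus fold coverage (overlap bases / target length), averaged
    unweighted across loci."""
    if not panel.loci:
        raise ValueError("panel is empty")
    records = list(records)
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if rec.span is not None:
            by_chrom.setdefault(rec.span.chrom, []).append(rec)
    per_locus = {}
    for locus in panel.loci:
        t = locus.target
        bases = sum(overlap_bases(r, t) for r in by_chrom.get(t.chrom, ()))
        per_locus[locus.name] = bases / t.length
    return TargetCoverage(
        mean=statistics.fmean(per_locus.values()), per_locus=per_locus
    )


def background_coverage(
    records: Iterable[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    panel,
    window: int = DEFAULT_WINDOW,
) -> BackgroundCoverage:
    """Mean depth over non-overlapping genome windows clear of all targets.

    Windows partially overlapping a merged target are wholly excluded, and
    only full-width windows are tiled.
    """
    merged = list(panel.merged_targets)
    depths: list[np.ndarray] = []
    eligible_total = 0
    window_depths_sum = 0.0
    n_windows = 0
    for chrom, clen in chrom_lengths.items():
        n = clen // window
        if n == 0:
            continue
        depth = np.zeros(n, dtype=np.float64)
        for rec in records:
            if rec.span is None or rec.span.chrom != chrom:
                continue
            s, e = rec.span.start, min(rec.span.end, n * window)
            if e <= s:
                continue
            w0, w1 = s // window, (e - 1) // window
            for w in range(w0, w1 + 1):
                ov = min(e, (w + 1) * window) - max(s, w * window)
                depth[w] += ov
        eligible = np.ones(n, dtype=bool)
        for t in merged:
            if t.chrom != chrom:
                continue
            w0 = t.start // window
            w1 = min((t.end - 1) // window, n - 1)
            if w1 >= w0:
                eligible[w0 : w1 + 1] = False
        n_windows += int(eligible.sum())
        window_depths_sum += float(depth[eligible].sum()) / window
    if n_windows == 0:
        raise ValueError("no eligible background windows")
    return BackgroundCoverage(mean=window_depths_sum / n_windows, n_windows=n_windows)


def enrichment(target_coverage: float, bg_coverage: float) -> Optional[float]:
    """Fold enrichment; None (undefined) when background is zero."""
    if bg_coverage == 0:
        return None
    return target_coverage / bg_coverage


def compute_enrichment(
    adaptive_records: Sequence[AlignmentRecord],
    nonadaptive_records: Sequence[AlignmentRecord],
    panel,
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> EnrichmentResult:
    tc = mean_target_coverage(adaptive_records, panel)
    bg = background_coverage(nonadaptive_records, chrom_lengths, panel, window)
    return EnrichmentResult(
        mean_target_coverage=tc.mean,
        background_coverage=bg.mean,
        enrichment=enrichment(tc.mean, bg.mean),
        n_windows=bg.n_windows,
    )


def phase_breadth(
    blocks: Sequence[PhaseBlock], cores: Mapping[str, GenomicInterval]
) -> PhaseBreadthResult:
    """Fraction of each gene's strict core interval covered by phase blocks."""
    rows = []
    for name, core in cores.items():
        if core.length <= 0:
            raise ValueError(f"gene {name}: zero-length core")
        pieces = [
            p
            for b in blocks
            if b.chrom == core.chrom and (p := b.interval.intersect(core)) is not None
        ]
        phased = total_length(merge_intervals(pieces))
        rows.append(
            PhaseBreadthRow(
                name=name,
                core_length=core.length,
                phased_bases=phased,
                breadth=phased / core.length,
                fully_phased=phased == core.length,
            )
        )
    return PhaseBreadthResult(rows=rows)


def blocks_from_phased_vcf(path: str | os.PathLike) -> tuple[list[PhaseBlock], int]:
    """Derive phase blocks from PS-tagged phased genotypes.

    One block per (chrom, phase set), spanning from the first member variant
    to the end of the last member's reference allele (0-based half-open).
    Returns (blocks, count of phased genotypes lacking a PS, treated as
    unphased).
    """
    extents: dict[tuple[str, int], tuple[int, int]] = {}
    missing_ps = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for sample in rec.samples.values():
                if not sample.phased:
                    continue
                ps = sample.get("PS")
                if ps is None:
                    missing_ps += 1
                    continue
                key = (rec.chrom, int(ps))
                start, stop = rec.start, rec.stop
                if key in extents:
                    s, e = extents[key]
                    extents[key] = (min(s, start), max(e, stop))
                else:
                    extents[key] = (start, stop)
    blocks = [
        PhaseBlock(chrom=chrom, interval=GenomicInterval(chrom, s, e), phase_set=ps)
        for (chrom, ps), (s, e) in sorted(extents.items())
    ]
    return blocks, missing_ps


def blocks_from_records(records: Iterable[AlignmentRecord]) -> list[PhaseBlock]:
    """Phase blocks from HP/PS read tags: span of tagged reads per phase set."""
    extents: dict[tuple[str, int], tuple[int, int]] = {}
    for rec in records:
        if rec.span is None or rec.haplotype is None or rec.phase_set is None:
            continue
        key = (rec.span.chrom, rec.phase_set)
        if key in extents:
            s, e = extents[key]
            extents[key] = (min(s, rec.span.start), max(e, rec.span.end))
        else:
            extents[key] = (rec.span.start, rec.span.end)
    return [
        PhaseBlock(chrom=chrom, interval=GenomicInterval(chrom, s, e), phase_set=ps)
        for (chrom, ps), (s, e) in sorted(extents.items())
    ]


class _DSU:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def time_to_phase(
    records: Iterable[AlignmentRecord],
    variant_positions: Sequence[tuple[str, int]],
    min_support: int = 1,
) -> TimeToPhase:
    """Earliest run time at which all variant positions are covered by
    haplotagged reads and linked into one phase-set component.

    Records are replayed in start-time order. A haplotagged record covering
    a variant position adds support there and joins the position to the
    record's phase set; positions are "phased together" once they share a
    connected component of phase sets. Records without timestamps are
    excluded and counted.
    """
    if len(variant_positions) < 2:
        raise ValueError("need at least 2 variant positions")
    timed, untimed = [], 0
    for rec in records:
        if rec.start_time is None:
            untimed += 1
        elif rec.span is not None:
            timed.append(rec)
    timed.sort(key=lambda r: r.start_time)
    support = [0] * len(variant_positions)
    dsu = _DSU()
    for rec in timed:
        if rec.haplotype is None or rec.phase_set is None:
            continue
        hit = False
        for i, (chrom, pos) in enumerate(variant_positions):
            if rec.span.contains_point(chrom, pos):
                support[i] += 1
                dsu.union(("var", i), ("ps", rec.span.chrom, rec.phase_set))
                hit = True
        if not hit:
            continue
        if all(s >= min_support for s in support):
            roots = {dsu.find(("var", i)) for i in range(len(variant_positions))}
            if len(roots) == 1:
                return TimeToPhase(seconds=rec.start_time, n_without_timestamp=untimed)
    return TimeToPhase(seconds=None, n_without_timestamp=untimed)
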