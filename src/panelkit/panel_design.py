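"""Target panel construction.

A panel is built from gene intervals by adding a flank (default 50 kb) on
each side, clipping to chromosome bounds and computing the merged,
non-overlapping target footprint. Each locus's expected share of targeted
bases is derived from the panel itself, never hard-coded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .intervals import (
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
    total_length,
)

DEFAULT_FLANK = 50_000


@dataclass(frozen=True)
class TargetLocus:
    """A gene body (``core``) plus its flanked targeting interval."""

    name: str
    core: GenomicInterval
    target: GenomicInterval

    def __post_init__(self) -> None:
        if not self.target.contains(self.core):
            raise ValueError(f"locus {self.name}: target must contain core")


@dataclass(frozen=True)
class TargetPanel:
    loci: tuple[TargetLocus, ...]
    merged_targets: tuple[GenomicInterval, ...] = field(default=())
    total_bases: int = 0

    @property
    def gross_bases(self) -> int:
        """Sum of per-locus target lengths, counting overlaps twice."""
        return sum(locus.target.length for locus in self.loci)

    def locus(self, name: str) -> TargetLocus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)


class BedParseError(ValueError):
    pass


def load_gene_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED4 gene intervals, in file order.

    Coordinates are taken as 0-based half-open per the BED standard. A
    missing name column defaults to ``chrom:start-end``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else ""
            iv = GenomicInterval(chrom, start, end, name)
            out.append(
                iv if name else GenomicInterval(chrom, start, end, iv.label)
            )
    return out


def load_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read chromosome lengths from a 2+ column TSV (e.g. a .fai index)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected >=2 fields")
            sizes[fields[0]] = int(fields[1])
    return sizes


def build_targets(
    genes: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    cores: Optional[Mapping[str, GenomicInterval]] = None,
) -> TargetPanel:
    """Flank each gene by ``flank`` bp on both sides and assemble the panel.

    ``chrom_lengths`` is required to clip flanks at chromosome ends; genes
    must lie within their chromosomes. ``cores`` optionally overrides the
    per-gene core interval (e.g. a strict coding span) used for phase
    breadth; by default the input interval is its own core.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not genes:
        raise ValueError("no gene intervals supplied")
    chrom_lengths = dict(chrom_lengths or {})
    loci = []
    for gene in genes:
        if gene.chrom not in chrom_lengths:
            raise KeyError(
                f"gene {gene.label}: chromosome {gene.chrom!r} not in chrom_lengths"
            )
        clen = chrom_lengths[gene.chrom]
        if gene.end > clen:
            raise ValueError(f"gene {gene.label} extends past end of {gene.chrom}")
        target = GenomicInterval(
            gene.chrom,
            max(0, gene.start - flank),
            min(clen, gene.end + flank),
            gene.label,
        )
        core = (cores or {}).get(gene.label, gene)
        loci.append(TargetLocus(name=gene.label, core=core, target=target))
    merged = merge_intervals([loc.target for loc in loci])
    return TargetPanel(
        loci=tuple(loci),
        merged_targets=tuple(merged),
        total_bases=total_length(merged),
    )


def effective_targets(panel: TargetPanel) -> dict[str, list[GenomicInterval]]:
    """Per-locus target intervals with overlaps assigned to the earlier locus.

    Shared bases between overlapping flanked loci are claimed by the locus
    listed first, so the effective intervals partition the merged footprint.
    """
    claimed: list[GenomicInterval] = []
    out: dict[str, list[GenomicInterval]] = {}
    for locus in panel.loci:
        out[locus.name] = subtract_intervals([locus.target], claimed)
        claimed = merge_intervals(claimed + [locus.target])
    return out


def expected_fractions(panel: TargetPanel) -> dict[str, float]:
    """Each locus's expected share of targeted bases; sums to 1."""
    if not panel.loci or panel.total_bases <= 0:
        raise ValueError("panel is empty")
    eff = effective_targets(panel)
    return {
        name: total_length(ivs) / panel.total_bases for name, ivs in eff.items()
    }


def write_targets_bed(panel: TargetPanel, path: str | os.PathLike) -> None:
    """One BED line per locus target, sorted by chrom then start."""
    loci = sorted(panel.loci, key=lambda l: (l.target.chrom, l.target.start))
    with open(path, "w") as fh:
        for locus in loci:
            t = locus.target
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{locus.name}\n")


def write_cores_bed(panel: TargetPanel, path: str | os.PathLike) -> None:
    loci = sorted(panel.loci, key=lambda l: (l.core.chrom, l.core.start))
    with open(path, "w") as fh:
        for locus in loci:
            c = locus.core
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{locus.name}\n")
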