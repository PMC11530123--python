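"""Per-site 5mC aggregation and focal hypomethylation cluster detection.

A hypomethylated cluster is a maximal run of consecutive CpG sites whose
modified fraction stays at or below a threshold, with inter-site gaps no
larger than ``max_gap`` and at least ``min_sites`` sites.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import GenomicInterval

DEFAULT_FRAC_THRESHOLD = 0.25
DEFAULT_MIN_SITES = 3
DEFAULT_MAX_GAP = 500
DEFAULT_MIN_COVERAGE = 5
DEFAULT_PROB_THRESHOLD = 0.5


@dataclass(frozen=True)
class MethylationSite:
    chrom: str
    pos: int  # 0-based CpG (forward-strand C) position
    coverage: int
    modified_fraction: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0.0 <= self.modified_fraction <= 1.0):
            raise ValueError("modified_fraction must be in [0,1]")


def aggregate_sites(
    calls: Iterable[tuple],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    collapse_strands: bool = True,
) -> list[MethylationSite]:
    """Aggregate per-read modification calls into per-site fractions.

    ``calls`` yields ``(chrom, pos, probability)`` or
    ``(chrom, pos, probability, strand)``; a call is modified when its
    probability is >= ``prob_threshold``. Reverse-strand calls are collapsed
    onto the forward-strand C (pos - 1) unless ``collapse_strands`` is off.
    Sites with coverage below ``min_coverage`` are dropped.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        chrom, pos, prob = call[0], call[1], call[2]
        strand = call[3] if len(call) > 3 else "+"
        if collapse_strands and strand == "-":
            pos -= 1
        key = (chrom, pos)
        tot_mod = counts.setdefault(key, [0, 0])
        tot_mod[0] += 1
        if prob >= prob_threshold:
            tot_mod[1] += 1
    sites = [
        MethylationSite(chrom, pos, tot, mod / tot)
        for (chrom, pos), (tot, mod) in sorted(counts.items())
        if tot >= min_coverage
    ]
    return sites


def hypomethylated_clusters(
    sites: Sequence[MethylationSite],
    frac_threshold: float = DEFAULT_FRAC_THRESHOLD,
    min_sites: int = DEFAULT_MIN_SITES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[GenomicInterval]:
    """Maximal low-methylation runs; each cluster spans first to last site."""
    by_chrom: dict[str, list[MethylationSite]] = {}
    last: dict[str, int] = {}
    for s in sites:
        if s.chrom in last and s.pos < last[s.chrom]:
            raise ValueError(f"sites not sorted by position on {s.chrom}")
        last[s.chrom] = s.pos
        by_chrom.setdefault(s.chrom, []).append(s)
    clusters: list[GenomicInterval] = []
    for chrom in by_chrom:
        run: list[MethylationSite] = []
        for s in by_chrom[chrom]:
            low = s.modified_fraction <= frac_threshold
            if low and run and s.pos - run[-1].pos <= max_gap:
                run.append(s)
            else:
                if len(run) >= min_sites:
                    clusters.append(
                        GenomicInterval(chrom, run[0].pos, run[-1].pos + 1)
                    )
                run = [s] if low else []
        if len(run) >= min_sites:
            clusters.append(GenomicInterval(chrom, run[0].pos, run[-1].pos + 1))
    return sorted(clusters)


def region_methylation_summary(
    sites: Sequence[MethylationSite], regions: Sequence[GenomicInterval]
) -> list[dict]:
    """Mean site fraction per region; regions with no sites report None."""
    out = []
    for region in regions:
        inside = [
            s.modified_fraction
            for s in sites
            if s.chrom == region.chrom and region.start <= s.pos < region.end
        ]
        out.append(
            {
                "region": region.label,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_sites": len(inside),
                "mean_fraction": sum(inside) / len(inside) if inside else None,
            }
        )
    return out


def read_bedmethyl(path: str | os.PathLike) -> list[MethylationSite]:
    """Read a bedMethyl-style TSV.

    Accepts the compact 5-column form (chrom, start, end, coverage,
    percent modified) or the 11+-column ENCODE layout (coverage in column
    10, percent in column 11).
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 11:
                cov, pct = int(f[9]), float(f[10])
            elif len(f) >= 5:
                cov, pct = int(f[3]), float(f[4])
            else:
                raise ValueError(f"{path}: line {lineno}: expected >=5 fields")
            sites.append(
                MethylationSite(
                    chrom=f[0],
                    pos=int(f[1]),
                    coverage=cov,
                    modified_fraction=pct / 100.0,
                )
            )
    return sites


def write_bedmethyl(
    sites: Sequence[MethylationSite], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.coverage}\t"
                f"{100.0 * s.modified_fraction:.4f}\n"
            )


def write_clusters_bed(
    clusters: Sequence[GenomicInterval], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(clusters, start=1):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\thypo_{i}\n")
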