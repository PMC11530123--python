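"""Targeting assessment: expected-vs-observed base regression and
duplicate-region diagnosis.

Observed base fractions are regressed on expected fractions in log10 space;
loci falling well below the fit (one-sided studentized residual) are
flagged, then read evidence (excess supplementary alignments whose primaries
cluster elsewhere) is used to propose hard-mask intervals.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .alignment_core import AlignmentRecord, filter_primary, overlap_bases
from .intervals import (
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
    total_length,
)
from .panel_design import TargetLocus, TargetPanel, effective_targets, expected_fractions

DEFAULT_UNIQUENESS_MAPQ = 1
DEFAULT_Z = 2.0
DEFAULT_MERGE_GAP = 10_000
DEFAULT_MIN_SUPP_FRACTION = 0.5
DEFAULT_MIN_CLUSTER_READS = 3


@dataclass
class LocusAssessment:
    name: str
    expected_fraction: float
    observed_bases: int
    observed_fraction: float
    log_expected: float
    log_observed: Optional[float]  # None when no bases observed
    residual: Optional[float] = None
    flagged: bool = False


@dataclass
class TargetingAssessment:
    rows: list[LocusAssessment]
    off_target_bases: int
    total_bases_observed: int

    def row(self, name: str) -> LocusAssessment:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def flagged_names(self) -> list[str]:
        return [r.name for r in self.rows if r.flagged]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float


@dataclass
class DuplicateDiagnosis:
    locus: str
    supplementary_fraction: float
    candidates: list[tuple[GenomicInterval, int]]  # (cluster, supporting reads)
    source_clusters: list[tuple[GenomicInterval, int]]
    note: str = ""


@dataclass
class MaskSet:
    intervals: list[GenomicInterval]
    provenance: dict[GenomicInterval, dict] = field(default_factory=dict)

    @property
    def total_bases(self) -> int:
        return total_length(merge_intervals(self.intervals))


def observed_bases(
    records: Iterable[AlignmentRecord],
    panel: TargetPanel,
    uniqueness_mapq: int = DEFAULT_UNIQUENESS_MAPQ,
) -> tuple[dict[str, int], int]:
    """Uniquely-mapped bases apportioned to each locus, plus off-target bases.

    Only primary, non-duplicate records at or above ``uniqueness_mapq``
    count. Bases shared by overlapping loci go to the earlier-listed locus
    (same policy as expected fractions), so conservation holds exactly:
    sum(locus bases) + off_target == sum(filtered span lengths).
    """
    eff = effective_targets(panel)
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for name, ivs in eff.items():
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((name, iv))
    per_locus = {loc.name: 0 for loc in panel.loci}
    off_target = 0
    for rec in filter_primary(records, min_mapq=uniqueness_mapq):
        span = rec.span
        claimed = 0
        for name, iv in by_chrom.get(span.chrom, ()):
            ov = span.intersection_length(iv)
            if ov:
                per_locus[name] += ov
                claimed += ov
        off_target += span.length - claimed
    return per_locus, off_target


def build_assessment(
    records: Iterable[AlignmentRecord],
    panel: TargetPanel,
    uniqueness_mapq: int = DEFAULT_UNIQUENESS_MAPQ,
) -> TargetingAssessment:
    fractions = expected_fractions(panel)
    per_locus, off_target = observed_bases(records, panel, uniqueness_mapq)
    total = sum(per_locus.values()) + off_target
    rows = []
    for loc in panel.loci:
        obs = per_locus[loc.name]
        o_frac = obs / total if total > 0 else 0.0
        rows.append(
            LocusAssessment(
                name=loc.name,
                expected_fraction=fractions[loc.name],
                observed_bases=obs,
                observed_fraction=o_frac,
                log_expected=math.log10(fractions[loc.name]),
                log_observed=math.log10(o_frac) if obs > 0 else None,
            )
        )
    return TargetingAssessment(
        rows=rows, off_target_bases=off_target, total_bases_observed=total
    )


def fit_targeting_regression(assessment: TargetingAssessment) -> RegressionFit:
    """OLS of log10 observed fraction on log10 expected fraction.

    Loci with zero observed bases are excluded from the fit and flagged.
    Residuals are written back onto the assessment rows.
    """
    usable = [r for r in assessment.rows if r.log_observed is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need >=3 loci with observed bases to fit regression, got {len(usable)}"
        )
    x = np.array([r.log_expected for r in usable])
    y = np.array([r.log_observed for r in usable])
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all expected fractions equal")
    res = stats.linregress(x, y)
    residuals = y - (res.intercept + res.slope * x)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (len(usable) - 2)))
    for row, r in zip(usable, residuals):
        row.residual = float(r)
    for row in assessment.rows:
        if row.log_observed is None:
            row.residual = None
            row.flagged = True
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_sd=residual_sd,
    )


def flag_undertargeted(
    assessment: TargetingAssessment,
    fit: RegressionFit,
    z_threshold: float = DEFAULT_Z,
) -> TargetingAssessment:
    """Flag loci whose residual falls at least z*sd below the fit.

    One-sided: only deficits flag. Zero-observed loci stay flagged.
    """
    for row in assessment.rows:
        if row.log_observed is None:
            row.flagged = True
        elif fit.residual_sd == 0:
            row.flagged = False
        else:
            row.flagged = row.residual <= -z_threshold * fit.residual_sd
    return assessment


def _cluster_spans(
    spans: Sequence[GenomicInterval], merge_gap: int, min_reads: int
) -> list[tuple[GenomicInterval, int]]:
    ordered = sorted(spans, key=lambda s: (s.chrom, s.start, s.end))
    clusters: list[tuple[str, int, int, int]] = []  # chrom, start, end, count
    for sp in ordered:
        if (
            clusters
            and clusters[-1][0] == sp.chrom
            and sp.start <= clusters[-1][2] + merge_gap
        ):
            chrom, s, e, n = clusters[-1]
            clusters[-1] = (chrom, s, max(e, sp.end), n + 1)
        else:
            clusters.append((sp.chrom, sp.start, sp.end, 1))
    return [
        (GenomicInterval(c, s, e), n) for c, s, e, n in clusters if n >= min_reads
    ]


def diagnose_duplicates(
    records: Iterable[AlignmentRecord],
    locus: TargetLocus,
    panel: TargetPanel,
    min_supp_fraction: float = DEFAULT_MIN_SUPP_FRACTION,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS,
) -> DuplicateDiagnosis:
    """Find off-panel duplicate copies explaining a flagged locus.

    Over the locus target, measures the fraction of aligned bases carried by
    supplementary/secondary records; if at least ``min_supp_fraction``, the
    primary alignments of those same reads are clustered and clusters lying
    outside the panel are returned as mask candidates.
    """
    records = list(records)
    target = locus.target
    supp, prim_bases, supp_bases = [], 0, 0
    for rec in records:
        if rec.span is None or rec.is_duplicate:
            continue
        ov = overlap_bases(rec, target)
        if ov == 0:
            continue
        if rec.is_supplementary or rec.is_secondary:
            supp.append(rec)
            supp_bases += ov
        else:
            prim_bases += ov
    total = prim_bases + supp_bases
    if total == 0:
        return DuplicateDiagnosis(
            locus=locus.name,
            supplementary_fraction=0.0,
            candidates=[],
            source_clusters=[],
            note="no coverage",
        )
    frac = supp_bases / total
    source_clusters = _cluster_spans(
        [r.span for r in supp], merge_gap, min_cluster_reads
    )
    if frac < min_supp_fraction:
        return DuplicateDiagnosis(
            locus=locus.name,
            supplementary_fraction=frac,
            candidates=[],
            source_clusters=source_clusters,
            note="supplementary fraction below threshold",
        )
    supp_ids = {r.read_id for r in supp}
    primaries = [
        r.span
        for r in records
        if r.is_primary and r.span is not None and r.read_id in supp_ids
    ]
    clusters = _cluster_spans(primaries, merge_gap, min_cluster_reads)
    merged_targets = list(panel.merged_targets)
    candidates = [
        (iv, n)
        for iv, n in clusters
        if subtract_intervals([iv], merged_targets)  # not fully inside the panel
    ]
    return DuplicateDiagnosis(
        locus=locus.name,
        supplementary_fraction=frac,
        candidates=candidates,
        source_clusters=source_clusters,
    )


def emit_mask_set(
    diagnoses: Mapping[str, DuplicateDiagnosis],
    panel: TargetPanel,
    policy: str = "mask-duplicate-copy",
) -> MaskSet:
    """Merge per-locus mask candidates into a sorted MaskSet with provenance.

    Under ``mask-duplicate-copy`` (default) the off-panel copy is masked;
    candidates straddling a panel target are truncated to their off-panel
    portion with a warning. Under ``mask-in-panel`` the supplementary-covered
    in-panel clusters are masked instead.
    """
    if policy not in ("mask-duplicate-copy", "mask-in-panel"):
        raise ValueError(f"unknown mask policy {policy!r}")
    merged_targets = list(panel.merged_targets)
    entries: list[tuple[GenomicInterval, str, int, list[str]]] = []
    for name, diag in diagnoses.items():
        source = diag.candidates if policy == "mask-duplicate-copy" else diag.source_clusters
        for iv, count in source:
            warnings: list[str] = []
            if policy == "mask-duplicate-copy":
                pieces = subtract_intervals([iv], merged_targets)
                if not pieces:
                    continue
                if total_length(pieces) < iv.length:
                    warnings.append(
                        f"candidate {iv.chrom}:{iv.start}-{iv.end} overlapped a "
                        "panel target; truncated to off-panel portion"
                    )
            else:
                pieces = [
                    p
                    for t in merged_targets
                    if (p := iv.intersect(t)) is not None
                ] or [iv]
            for piece in pieces:
                entries.append((piece, name, count, warnings))
    # merge overlapping pieces across loci, pooling provenance
    entries.sort(key=lambda e: (e[0].chrom, e[0].start, e[0].end))
    merged: list[tuple[GenomicInterval, dict]] = []
    for iv, name, count, warnings in entries:
        info = {"loci": [name], "reads": count, "warnings": list(warnings)}
        if merged and merged[-1][0].chrom == iv.chrom and iv.start <= merged[-1][0].end:
            prev, pinfo = merged[-1]
            union = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end))
            if name not in pinfo["loci"]:
                pinfo["loci"].append(name)
            pinfo["reads"] += count
            pinfo["warnings"].extend(warnings)
            merged[-1] = (union, pinfo)
        else:
            merged.append((iv, info))
    return MaskSet(
        intervals=[iv for iv, _ in merged],
        provenance={iv: info for iv, info in merged},
    )


def write_mask_bed(mask: MaskSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in mask.intervals:
            info = mask.provenance.get(iv, {})
            label = ",".join(info.get("loci", [])) or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def load_mask_bed(path: str | os.PathLike) -> MaskSet:
    from .panel_design import load_gene_intervals

    ivs = load_gene_intervals(path)
    return MaskSet(intervals=list(ivs))


def write_assessment_tsv(
    assessment: TargetingAssessment, path: str | os.PathLike
) -> None:
    cols = (
        "locus\texpected_fraction\tobserved_bases\tobserved_fraction\t"
        "log10_expected\tlog10_observed\tresidual\tflagged\n"
    )

    def fmt(v) -> str:
        return "NA" if v is None else f"{v:.10g}" if isinstance(v, float) else str(v)

    with open(path, "w") as fh:
        fh.write(cols)
        for r in assessment.rows:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        fmt(r.expected_fraction),
                        str(r.observed_bases),
                        fmt(r.observed_fraction),
                        fmt(r.log_expected),
                        fmt(r.log_observed),
                        fmt(r.residual),
                        str(int(r.flagged)),
                    ]
                )
                + "\n"
            )
        fh.write(
            f"off_target\tNA\t{assessment.off_target_bases}\t"
            f"{fmt(assessment.off_target_bases / assessment.total_bases_observed if assessment.total_bases_observed else 0.0)}"
            "\tNA\tNA\tNA\t0\n"
        )


def write_regression_json(fit: RegressionFit, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "residual_sd": fit.residual_sd,
                "regressed": "log10 observed fraction on log10 expected fraction",
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def plot_regression(
    assessment: TargetingAssessment, fit: RegressionFit, path: str | os.PathLike
) -> None:
    """Scatter of log-expected vs log-observed with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in assessment.rows if r.log_observed is not None]
    x = [r.log_expected for r in rows]
    y = [r.log_observed for r in rows]
    flagged = [r.flagged for r in rows]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        [xi for xi, f in zip(x, flagged) if not f],
        [yi for yi, f in zip(y, flagged) if not f],
        s=12,
        label="ok",
    )
    ax.scatter(
        [xi for xi, f in zip(x, flagged) if f],
        [yi for yi, f in zip(y, flagged) if f],
        s=16,
        color="crimson",
        label="flagged",
    )
    xs = np.linspace(min(x), max(x), 10)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="gray", lw=1)
    ax.set_xlabel("log10 expected fraction")
    ax.set_ylabel("log10 observed fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
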