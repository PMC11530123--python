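"""Deterministic generators for toy references, adaptive-sampling runs,
phased variants and methylomes with known ground truth.

Every generator is fully determined by (parameters, seed). Rejection on
adaptive channels is modeled as truncation of off-target reads to the
decision length. A planted duplication diverts reads overlapping its source
segment: their primary alignment is emitted at the duplicate copy (clipped
to the copy, since flanking sequence differs) with a supplementary record
left at the source — the signature the targeting QC looks for. Diversion
switches off once the copy has been hard-masked in the reference.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .alignment_core import AlignmentRecord
from .intervals import GenomicInterval
from .panel_design import TargetPanel, build_targets

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DuplicationPair:
    source: GenomicInterval
    copy: GenomicInterval
    identity: float = 1.0


@dataclass
class SimulationTruth:
    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    duplications: list[DuplicationPair] = field(default_factory=list)
    target_depth: Optional[float] = None
    background_depth: Optional[float] = None
    phase_breadths: dict[str, float] = field(default_factory=dict)
    phase_blocks: dict[str, GenomicInterval] = field(default_factory=dict)
    pair_labels: dict[str, str] = field(default_factory=dict)
    pair_variant_ids: dict[str, tuple[str, str]] = field(default_factory=dict)
    hypo_intervals: list[GenomicInterval] = field(default_factory=list)


@dataclass(frozen=True)
class RunParams:
    target_depth: float = 25.0
    background_depth: float = 1.5
    read_length_mean: float = 7000.0
    read_length_sd: float = 2500.0
    min_read_length: int = 300
    adaptive_channels: tuple[int, ...] = tuple(range(1, 257))
    nonadaptive_channels: tuple[int, ...] = tuple(range(257, 513))
    decision_length: int = 500
    run_hours: float = 24.0
    reject_attempts_per_mb: int = 200
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.decision_length >= self.read_length_mean:
            raise ValueError("decision_length must be below the mean read length")
        if self.target_depth < 0 or self.background_depth < 0:
            raise ValueError("depths must be >= 0")


def make_reference(
    chrom_lengths: Mapping[str, int],
    duplications: Sequence[DuplicationPair] = (),
    seed: int = 0,
) -> tuple[dict[str, str], SimulationTruth]:
    """Random-base sequences with duplicated segments copied in.

    Each duplication copies the source segment to the copy interval,
    mutating bases independently at rate ``1 - identity``.
    """
    rng = np.random.default_rng(seed)
    planted = [d.source for d in duplications] + [d.copy for d in duplications]
    for i, a in enumerate(planted):
        if a.end > chrom_lengths.get(a.chrom, 0):
            raise ValueError(f"planted interval {a.label} outside reference bounds")
        for b in planted[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"planted intervals overlap: {a.label} / {b.label}")
    seqs: dict[str, np.ndarray] = {
        chrom: _BASES[rng.integers(0, 4, size=length)]
        for chrom, length in chrom_lengths.items()
    }
    for dup in duplications:
        if dup.copy.length != dup.source.length:
            raise ValueError("duplication source and copy must have equal length")
        segment = seqs[dup.source.chrom][dup.source.start : dup.source.end].copy()
        if dup.identity < 1.0:
            mutate = rng.random(len(segment)) < (1.0 - dup.identity)
            shift = rng.integers(1, 4, size=int(mutate.sum()))
            idx = np.flatnonzero(mutate)
            base_idx = np.searchsorted(_BASES, segment[idx])
            segment[idx] = _BASES[(base_idx + shift) % 4]
        seqs[dup.copy.chrom][dup.copy.start : dup.copy.end] = segment
    truth = SimulationTruth(
        seed=seed,
        chrom_lengths=dict(chrom_lengths),
        duplications=list(duplications),
    )
    return {c: a.tobytes().decode() for c, a in seqs.items()}, truth


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _masked_fraction(seq: str, start: int, end: int) -> float:
    sub = seq[start:end]
    return sub.count("N") / len(sub) if sub else 0.0


def simulate_run(
    reference: Mapping[str, str],
    panel: TargetPanel,
    params: RunParams = RunParams(),
    duplications: Sequence[DuplicationPair] = (),
    seed: int = 0,
) -> tuple[list[AlignmentRecord], SimulationTruth]:
    """Simulate one adaptive-sampling run; returns alignment records.

    Target intervals are filled until their planted per-base depth is
    reached; nonadaptive channels sample the whole genome to the background
    depth; adaptive off-target attempts appear as decision-length stubs.
    """
    if params.target_depth > 0 and not panel.loci:
        raise ValueError("empty panel with target_depth > 0")
    rng = np.random.default_rng(seed)
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    chroms = list(chrom_lengths)
    genome_len = sum(chrom_lengths.values())
    mu, sigma = _lognormal_params(params.read_length_mean, params.read_length_sd)
    adaptive = np.array(sorted(params.adaptive_channels))
    nonadaptive = np.array(sorted(params.nonadaptive_channels))
    run_seconds = params.run_hours * 3600.0

    # duplications stay active until their copy has been masked out
    active_dups = [
        d
        for d in duplications
        if _masked_fraction(reference[d.copy.chrom], d.copy.start, d.copy.end) < 0.5
    ]

    records: list[AlignmentRecord] = []
    counter = 0

    def draw_length() -> int:
        return max(params.min_read_length, int(rng.lognormal(mu, sigma)))

    def emit(chrom: str, start: int, end: int, channel: int) -> None:
        nonlocal counter
        counter += 1
        rid = f"r{counter:07d}"
        t = float(rng.uniform(0.0, run_seconds))
        span = GenomicInterval(chrom, start, end)
        diverted = None
        for dup in active_dups:
            if (
                chrom == dup.source.chrom
                and span.intersection_length(dup.source) >= 0.5 * span.length
            ):
                diverted = dup
                break
        if diverted is None:
            if _masked_fraction(reference[chrom], start, end) > 0.5:
                return  # molecule from a masked region: unalignable
            records.append(
                AlignmentRecord(
                    read_id=rid,
                    chrom=chrom,
                    span=span,
                    mapq=params.mapq,
                    channel=channel,
                    start_time=t,
                )
            )
            return
        offset = start - diverted.source.start
        ps = diverted.copy.start + offset
        pe = ps + span.length
        ps2, pe2 = max(ps, diverted.copy.start), min(pe, diverted.copy.end)
        if pe2 <= ps2:
            return
        records.append(
            AlignmentRecord(
                read_id=rid,
                chrom=diverted.copy.chrom,
                span=GenomicInterval(diverted.copy.chrom, ps2, pe2),
                mapq=params.mapq,
                channel=channel,
                start_time=t,
            )
        )
        records.append(
            AlignmentRecord(
                read_id=rid,
                chrom=chrom,
                span=span,
                mapq=params.mapq,
                is_supplementary=True,
                channel=channel,
                start_time=t,
            )
        )

    # adaptive channels: fill each merged target to the planted depth
    for target in panel.merged_targets:
        needed = params.target_depth * target.length
        acc = 0.0
        clen = chrom_lengths[target.chrom]
        while acc < needed:
            length = draw_length()
            # accepted reads start inside the target (the accept decision is
            # made on the first bases); they may run past the target end
            start = int(rng.integers(target.start, target.end))
            end = min(clen, start + length)
            ov = min(end, target.end) - start
            acc += ov
            emit(target.chrom, start, end, int(rng.choice(adaptive)))

    # adaptive channels: rejected off-target attempts, truncated stubs
    n_reject = int(genome_len / 1e6 * params.reject_attempts_per_mb)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    merged = list(panel.merged_targets)
    for _ in range(n_reject):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, chrom_lengths[chrom]))
        if any(t.contains_point(chrom, start) for t in merged):
            continue
        end = min(chrom_lengths[chrom], start + params.decision_length)
        if end > start:
            emit(chrom, start, end, int(rng.choice(adaptive)))

    # nonadaptive channels: whole-genome sampling to the background depth
    needed = params.background_depth * genome_len
    acc = 0.0
    while acc < needed:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = draw_length()
        start = int(rng.integers(0, chrom_lengths[chrom]))
        end = min(chrom_lengths[chrom], start + length)
        if end <= start:
            continue
        acc += end - start
        emit(chrom, start, end, int(rng.choice(nonadaptive)))

    truth = SimulationTruth(
        seed=seed,
        chrom_lengths=chrom_lengths,
        duplications=list(duplications),
        target_depth=params.target_depth,
        background_depth=params.background_depth,
    )
    return records, truth


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int  # 1-based
    vid: str
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool
    phase_set: Optional[int]
    info: str = "."


def simulate_phased_variants(
    panel: TargetPanel,
    breadths: Mapping[str, float],
    pair_labels: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[VcfRecord], SimulationTruth]:
    """Phased variants realizing requested per-gene phase breadths and
    cis/trans pair configurations.

    Each gene with breadth > 0 gets one phase block anchored at the core
    start, delimited by phased heterozygous SNVs at the block boundaries;
    requested pairs are placed inside the block with genotypes encoding the
    label (cis: both alts on haplotype 0; trans: opposite haplotypes).
    """
    pair_labels = dict(pair_labels or {})
    truth = SimulationTruth(seed=seed)
    records: list[VcfRecord] = []
    for locus in panel.loci:
        b = breadths.get(locus.name)
        if b is None:
            continue
        if not (0.0 <= b <= 1.0):
            raise ValueError(f"breadth for {locus.name} must be in [0,1]")
        truth.phase_breadths[locus.name] = b
        core = locus.core
        phased_len = int(round(b * core.length))
        if phased_len <= 0:
            if locus.name in pair_labels:
                raise ValueError(
                    f"pair requested for {locus.name} but breadth excludes variants"
                )
            continue
        block = GenomicInterval(core.chrom, core.start, core.start + phased_len)
        truth.phase_blocks[locus.name] = block
        ps = block.start + 1
        positions = {block.start + 1, block.end}  # 1-based boundary variants
        for pos1 in sorted(positions):
            records.append(
                VcfRecord(
                    chrom=block.chrom,
                    pos=pos1,
                    vid=f"{locus.name}_pb{pos1}",
                    ref="A",
                    alt="G",
                    genotype=(1, 0),
                    phased=True,
                    phase_set=ps,
                )
            )
        label = pair_labels.get(locus.name)
        if label is not None:
            if label not in ("cis", "trans"):
                raise ValueError(f"pair label must be cis or trans, got {label!r}")
            if phased_len < 8:
                raise ValueError(
                    f"block for {locus.name} too short to place a variant pair"
                )
            p1 = block.start + phased_len // 3 + 1
            p2 = block.start + (2 * phased_len) // 3 + 1
            gts = ((1, 0), (1, 0)) if label == "cis" else ((1, 0), (0, 1))
            ids = (f"{locus.name}_a", f"{locus.name}_b")
            for pos1, gt, vid in zip((p1, p2), gts, ids):
                records.append(
                    VcfRecord(
                        chrom=block.chrom,
                        pos=pos1,
                        vid=vid,
                        ref="A",
                        alt="T",
                        genotype=gt,
                        phased=True,
                        phase_set=ps,
                    )
                )
            truth.pair_labels[locus.name] = label
            truth.pair_variant_ids[locus.name] = ids
    records.sort(key=lambda r: (r.chrom, r.pos, r.vid))
    return records, truth


def simulate_methylome(
    reference: Mapping[str, str],
    hypo_intervals: Sequence[GenomicInterval],
    baseline_beta: tuple[float, float] = (9.0, 1.0),
    hypo_beta: tuple[float, float] = (1.0, 60.0),
    coverage_poisson_mean: float = 15.0,
    seed: int = 0,
):
    """Per-CpG methylation fractions: baseline Beta outside planted
    hypomethylated intervals, hypo Beta inside; coverages Poisson."""
    from .methylation_profile import MethylationSite

    if coverage_poisson_mean <= 0:
        raise ValueError("coverage mean must be > 0")
    rng = np.random.default_rng(seed)
    sites: list[MethylationSite] = []
    for chrom in reference:
        seq = np.frombuffer(reference[chrom].encode(), dtype=np.uint8)
        pos_arr = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        if len(pos_arr) == 0:
            continue
        in_hypo = np.zeros(len(pos_arr), dtype=bool)
        for iv in hypo_intervals:
            if iv.chrom == chrom:
                in_hypo |= (pos_arr >= iv.start) & (pos_arr < iv.end)
        fractions = np.where(
            in_hypo,
            rng.beta(hypo_beta[0], hypo_beta[1], size=len(pos_arr)),
            rng.beta(baseline_beta[0], baseline_beta[1], size=len(pos_arr)),
        )
        coverages = rng.poisson(coverage_poisson_mean, size=len(pos_arr))
        for p, f, c in zip(pos_arr, fractions, coverages):
            if c > 0:
                sites.append(MethylationSite(chrom, int(p), int(c), float(f)))
    truth = SimulationTruth(
        seed=seed,
        chrom_lengths={c: len(s) for c, s in reference.items()},
        hypo_intervals=list(hypo_intervals),
    )
    return sites, truth


def write_sam(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write records as SAM with ch/st/HP/PS tags and SA-linked
    supplementary alignments; round-trips through read_alignments."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    def sa_entry(r: AlignmentRecord) -> str:
        return f"{r.span.chrom},{r.span.start + 1},+,{r.span.length}M,{r.mapq},0;"

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            flag = 0
            if rec.is_unmapped:
                flag |= 0x4
            if rec.is_secondary:
                flag |= 0x100
            if rec.is_duplicate:
                flag |= 0x400
            if rec.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            if rec.span is not None:
                seg.reference_id = tid[rec.span.chrom]
                seg.reference_start = rec.span.start
                seg.cigartuples = [(0, rec.span.length)]
            seg.mapping_quality = rec.mapq
            tags = []
            if rec.channel is not None:
                tags.append(("ch", int(rec.channel)))
            if rec.start_time is not None:
                tags.append(("st", float(rec.start_time)))
            if rec.haplotype is not None:
                tags.append(("HP", int(rec.haplotype)))
            if rec.phase_set is not None:
                tags.append(("PS", int(rec.phase_set)))
            mates = [m for m in by_read[rec.read_id] if m is not rec and m.span]
            if rec.span is not None and mates:
                tags.append(("SA", "".join(sa_entry(m) for m in mates)))
            seg.set_tags(tags)
            out.write(seg)


def write_vcf(
    records: Sequence[VcfRecord],
    chrom_lengths: Mapping[str, int],
    path: str | os.PathLike,
    sample: str = "SAMPLE",
) -> None:
    """Serialize a minimal phased VCF 4.2 ('|' separators only when phased)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.vid)):
            sep = "|" if rec.phased else "/"
            gt = sep.join(map(str, rec.genotype))
            if rec.phase_set is not None:
                fmt, val = "GT:PS", f"{gt}:{rec.phase_set}"
            else:
                fmt, val = "GT", gt
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.vid}\t{rec.ref}\t{rec.alt}\t.\t"
                f"PASS\t{rec.info}\t{fmt}\t{val}\n"
            )
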