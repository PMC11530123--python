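"""Allelic-architecture reporting from phased VCFs.

Classifies heterozygous variant pairs as cis (same haplotype) or trans
(opposite haplotypes) when they share a phase set, reports genomic
distances, and extracts structural-variant breakpoint spans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
import pysam


@dataclass(frozen=True)
class PhasedVariant:
    chrom: str
    pos: int  # 1-based, as printed in VCF
    ref: str
    alt: str
    genotype: tuple[int, int]
    phased: bool
    phase_set: Optional[int] = None
    svtype: Optional[str] = None
    end: Optional[int] = None
    vid: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def alt_haplotype(self) -> Optional[int]:
        """Index (0/1) of the haplotype carrying the alt allele, if phased het."""
        if not (self.phased and self.is_het):
            return None
        return self.genotype.index(1)


def load_phased_variants(path: str | os.PathLike) -> list[PhasedVariant]:
    """Load sample-0 genotypes; multi-allelic sites are split per alt allele."""
    out: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            ps = sample.get("PS")
            svtype = rec.info.get("SVTYPE") if "SVTYPE" in rec.info else None
            end = rec.stop if svtype else None
            for ai, alt in enumerate(rec.alts or (), start=1):
                coded = tuple(1 if a == ai else 0 for a in gt)
                out.append(
                    PhasedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotype=coded,
                        phased=bool(sample.phased),
                        phase_set=int(ps) if ps is not None else None,
                        svtype=svtype,
                        end=int(end) if end is not None else None,
                        vid=rec.id if rec.id else f"{rec.chrom}:{rec.pos}:{alt}",
                    )
                )
    return out


def classify_pair(v1: PhasedVariant, v2: PhasedVariant) -> str:
    """'cis', 'trans', or 'unphased' for two heterozygous variants."""
    if not (v1.is_het and v2.is_het):
        raise ValueError("cis/trans classification requires two heterozygotes")
    if (
        v1.phased
        and v2.phased
        and v1.phase_set is not None
        and v1.phase_set == v2.phase_set
        and v1.chrom == v2.chrom
    ):
        return "cis" if v1.alt_haplotype == v2.alt_haplotype else "trans"
    return "unphased"


def variant_distance(v1: PhasedVariant, v2: PhasedVariant) -> int:
    if v1.chrom != v2.chrom:
        raise ValueError(
            f"variants on different chromosomes ({v1.chrom} vs {v2.chrom})"
        )
    return abs(v2.pos - v1.pos)


def sv_span(v: PhasedVariant) -> tuple[int, int, int]:
    """(start, end, length) of a symbolic SV, length = end - start."""
    if v.svtype not in ("DEL", "DUP", "INV"):
        raise ValueError(f"not a DEL/DUP/INV structural variant: {v.svtype!r}")
    if v.end is None:
        raise ValueError("SV record lacks an END coordinate")
    if v.end <= v.pos:
        raise ValueError(f"empty SV span {v.pos}-{v.end}")
    return v.pos, v.end, v.end - v.pos


@dataclass
class ArchitectureReport:
    pairs: pd.DataFrame
    variants: pd.DataFrame

    def to_text(self) -> str:
        lines = ["# variants"]
        lines.append(self.variants.to_string(index=False))
        lines.append("")
        lines.append("# pairs")
        lines.append(self.pairs.to_string(index=False))
        return "\n".join(lines) + "\n"


def architecture_report(
    variants: Sequence[PhasedVariant], pairs: Sequence[tuple[str, str]]
) -> ArchitectureReport:
    by_id = {v.vid: v for v in variants}
    vrows = [
        {
            "id": v.vid,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "genotype": ("|" if v.phased else "/").join(map(str, v.genotype)),
            "phase_set": v.phase_set if v.phase_set is not None else "NA",
            "alt_haplotype": v.alt_haplotype if v.alt_haplotype is not None else "NA",
        }
        for v in variants
    ]
    prows = []
    for id1, id2 in pairs:
        if id1 not in by_id or id2 not in by_id:
            missing = id1 if id1 not in by_id else id2
            raise KeyError(f"unknown variant id in pairs: {missing!r}")
        v1, v2 = by_id[id1], by_id[id2]
        cls = classify_pair(v1, v2)
        dist = variant_distance(v1, v2) if v1.chrom == v2.chrom else "NA"
        prows.append(
            {
                "id1": id1,
                "id2": id2,
                "classification": cls,
                "distance_bp": dist,
                "phase_set_1": v1.phase_set if v1.phase_set is not None else "NA",
                "phase_set_2": v2.phase_set if v2.phase_set is not None else "NA",
            }
        )
    pair_cols = [
        "id1", "id2", "classification", "distance_bp", "phase_set_1", "phase_set_2",
    ]
    var_cols = [
        "id", "chrom", "pos", "ref", "alt", "genotype", "phase_set", "alt_haplotype",
    ]
    return ArchitectureReport(
        pairs=pd.DataFrame(prows, columns=pair_cols),
        variants=pd.DataFrame(vrows, columns=var_cols),
    )
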