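"""Hard-masking of reference FASTA sequences from a mask interval set."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

from pyfaidx import Fasta

from .intervals import GenomicInterval, merge_intervals
from .targeting_qc import MaskSet

LINE_WIDTH = 60  # fixed output wrap so byte-level diffs are deterministic
MASK_CHAR = "N"


@dataclass
class MaskReport:
    masked_bases: dict[str, int] = field(default_factory=dict)

    @property
    def total_masked(self) -> int:
        return sum(self.masked_bases.values())


@dataclass
class VerifyReport:
    ok: bool
    message: str = ""


def _intervals_of(mask: MaskSet | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ivs = mask.intervals if isinstance(mask, MaskSet) else list(mask)
    return merge_intervals(ivs)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    with Fasta(str(path), as_raw=True, sequence_always_upper=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(
    sequences: dict[str, str], path: str | os.PathLike, width: int = LINE_WIDTH
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def mask_fasta(
    reference: str | os.PathLike,
    mask: MaskSet | Sequence[GenomicInterval],
    out_path: str | os.PathLike,
) -> MaskReport:
    """Write a copy of ``reference`` with mask intervals replaced by 'N'.

    Sequence names, order and lengths are preserved; every mask interval
    must lie within its sequence's bounds.
    """
    seqs = read_fasta(reference)
    intervals = _intervals_of(mask)
    report = MaskReport(masked_bases={name: 0 for name in seqs})
    out = dict(seqs)
    for iv in intervals:
        if iv.chrom not in seqs:
            raise KeyError(f"mask interval on unknown sequence {iv.chrom!r}")
        if iv.end > len(seqs[iv.chrom]):
            raise ValueError(
                f"mask interval {iv.chrom}:{iv.start}-{iv.end} exceeds sequence "
                f"length {len(seqs[iv.chrom])}"
            )
        s = out[iv.chrom]
        out[iv.chrom] = s[: iv.start] + MASK_CHAR * iv.length + s[iv.end :]
        report.masked_bases[iv.chrom] += iv.length
    write_fasta(out, out_path)
    return report


def verify_mask(
    original: str | os.PathLike,
    masked: str | os.PathLike,
    mask: MaskSet | Sequence[GenomicInterval],
) -> VerifyReport:
    """Check masked positions are 'N' and everything else is untouched."""
    orig = read_fasta(original)
    new = read_fasta(masked)
    if list(orig.keys()) != list(new.keys()):
        return VerifyReport(False, "sequence names or order differ")
    intervals = _intervals_of(mask)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for name in orig:
        if len(orig[name]) != len(new[name]):
            return VerifyReport(False, f"{name}: length mismatch")
        masked_flags = bytearray(len(orig[name]))
        for iv in by_chrom.get(name, ()):
            for i in range(iv.start, iv.end):
                masked_flags[i] = 1
        o, m = orig[name], new[name]
        for i in range(len(o)):
            if masked_flags[i]:
                if m[i].upper() != MASK_CHAR:
                    return VerifyReport(
                        False, f"{name}:{i}: masked position is {m[i]!r}, not N"
                    )
            elif o[i] != m[i]:
                return VerifyReport(
                    False, f"{name}:{i}: unmasked position changed {o[i]!r}->{m[i]!r}"
                )
    return VerifyReport(True, "ok")
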