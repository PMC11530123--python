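import pytest

from panelkit.alignment_core import AlignmentRecord
from panelkit.intervals import GenomicInterval
from panelkit.panel_design import build_targets


def make_record(
    chrom="chr1",
    start=0,
    end=1000,
    read_id="r1",
    mapq=60,
    **kwargs,
):
    """Shorthand for building mapped AlignmentRecords in tests."""
    return AlignmentRecord(
        read_id=read_id,
        chrom=chrom,
        span=GenomicInterval(chrom, start, end),
        mapq=mapq,
        **kwargs,
    )


@pytest.fixture
def rec_factory():
    return make_record


@pytest.fixture
def small_panel():
    """Three disjoint loci on one 1 Mb chromosome, flank 0."""
    genes = [
        GenomicInterval("chr1", 100_000, 130_000, "A"),
        GenomicInterval("chr1", 300_000, 370_000, "B"),
        GenomicInterval("chr1", 500_000, 550_000, "C"),
    ]
    return build_targets(genes, flank=0, chrom_lengths={"chr1": 1_000_000})
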