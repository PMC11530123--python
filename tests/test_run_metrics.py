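import numpy as np
import pytest

from panelkit import run_metrics as rm
from panelkit.intervals import GenomicInterval
from panelkit.panel_design import build_targets
from panelkit.synthetic_fixtures import VcfRecord, write_vcf

from conftest import make_record

PARTITION = rm.ChannelPartition(
    adaptive_channels=frozenset(range(1, 257)),
    nonadaptive_channels=frozenset(range(257, 513)),
)


class TestPartitionChannels:
    def test_routing(self):
        a, n, u = rm.partition_channels([make_record(channel=10)], PARTITION)
        assert len(a) == 1 and not n and u == 0

    def test_missing_channel_unassigned(self):
        a, n, u = rm.partition_channels([make_record(channel=None)], PARTITION)
        assert not a and not n and u == 1

    def test_empty_partition_all_unassigned(self):
        empty = rm.ChannelPartition(frozenset(), frozenset())
        a, n, u = rm.partition_channels(
            [make_record(channel=5), make_record(channel=300)], empty
        )
        assert u == 2

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            rm.ChannelPartition(frozenset({1}), frozenset({1}))


class TestMeanTargetCoverage:
    def _panel(self, genes):
        return build_targets(genes, flank=0, chrom_lengths={"chr1": 1_000_000})

    def test_simple_division(self):
        panel = self._panel([GenomicInterval("chr1", 0, 100_000, "A")])
        # 250 reads of 10 kb fully inside: 2,500,000 bases over 100 kb
        records = [
            make_record(read_id=f"r{i}", start=0, end=10_000) for i in range(250)
        ]
        cov = rm.mean_target_coverage(records, panel)
        assert cov.per_locus["A"] == pytest.approx(25.0)

    def test_unweighted_mean_over_loci(self):
        panel = self._panel(
            [
                GenomicInterval("chr1", 0, 10_000, "A"),
                GenomicInterval("chr1", 500_000, 540_000, "B"),
            ]
        )
        records = [make_record(read_id=f"a{i}", start=0, end=10_000) for i in range(10)]
        records += [
            make_record(read_id=f"b{i}", start=500_000, end=540_000) for i in range(30)
        ]
        cov = rm.mean_target_coverage(records, panel)
        assert cov.per_locus == {"A": 10.0, "B": 30.0}
        assert cov.mean == pytest.approx(20.0)

    def test_no_reads(self):
        panel = self._panel([GenomicInterval("chr1", 0, 10_000, "A")])
        assert rm.mean_target_coverage([], panel).mean == 0.0

    def test_empty_panel_error(self):
        with pytest.raises(ValueError):
            rm.mean_target_coverage([], _EmptyPanel())

    def test_linear_in_read_count(self):
        panel = self._panel(
            [
                GenomicInterval("chr1", 0, 10_000, "A"),
                GenomicInterval("chr1", 50_000, 70_000, "B"),
            ]
        )
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 90_000, size=50)
        lengths = rng.integers(500, 8000, size=50)
        records = [
            make_record(read_id=f"r{i}", start=int(s), end=int(s + l))
            for i, (s, l) in enumerate(zip(starts, lengths))
        ]
        doubled = records + [
            make_record(
                read_id=f"{r.read_id}x", start=r.span.start, end=r.span.end
            )
            for r in records
        ]
        c1 = rm.mean_target_coverage(records, panel)
        c2 = rm.mean_target_coverage(doubled, panel)
        for name in c1.per_locus:
            assert c2.per_locus[name] == pytest.approx(2 * c1.per_locus[name])


class _EmptyPanel:
    loci = ()
    merged_targets = ()


class TestBackgroundCoverage:
    def test_uniform_depth_two(self):
        panel = build_targets(
            [GenomicInterval("chr1", 20_000, 40_000, "A")],
            flank=0,
            chrom_lengths={"chr1": 100_000},
        )
        records = [
            make_record(read_id=f"r{i}", start=0, end=100_000) for i in range(2)
        ]
        bg = rm.background_coverage(records, {"chr1": 100_000}, panel)
        assert bg.mean == pytest.approx(2.0)
        assert bg.n_windows == 8

    def test_no_reads(self):
        panel = build_targets(
            [GenomicInterval("chr1", 20_000, 40_000, "A")],
            flank=0,
            chrom_lengths={"chr1": 100_000},
        )
        bg = rm.background_coverage([], {"chr1": 100_000}, panel)
        assert bg.mean == 0.0

    def test_no_eligible_windows(self):
        panel = build_targets(
            [GenomicInterval("chr1", 0, 100_000, "A")],
            flank=0,
            chrom_lengths={"chr1": 100_000},
        )
        with pytest.raises(ValueError):
            rm.background_coverage([], {"chr1": 100_000}, panel)

    def test_poisson_background_recovery(self):
        # Monte-Carlo: unit-length reads at Poisson(1.5) per-base intensity
        lam = 1.5
        clen = 200_000
        rng = np.random.default_rng(9)
        panel = build_targets(
            [GenomicInterval("chr1", 0, 10_000, "A")],
            flank=0,
            chrom_lengths={"chr1": clen},
        )
        n_reads = rng.poisson(lam * clen / 100)
        records = [
            make_record(
                read_id=f"r{i}",
                start=int(s),
                end=min(clen, int(s) + 100),
            )
            for i, s in enumerate(rng.integers(0, clen, size=n_reads))
        ]
        bg = rm.background_coverage(records, {"chr1": clen}, panel)
        se = lam / np.sqrt(n_reads)
        assert abs(bg.mean - lam) < 3 * se


class TestEnrichment:
    def test_ratio(self):
        assert rm.enrichment(25.0, 1.5625) == pytest.approx(16.0)

    def test_identity(self):
        assert rm.enrichment(3.3, 3.3) == pytest.approx(1.0)

    def test_zero_background_undefined(self):
        assert rm.enrichment(25.0, 0.0) is None


class TestPhaseBreadth:
    def test_union_arithmetic(self):
        core = {"G": GenomicInterval("chr1", 1000, 11_000)}
        blocks = [
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 0, 6000), 1),
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 7000, 20_000), 2),
        ]
        res = rm.phase_breadth(blocks, core)
        row = res.row("G")
        assert row.phased_bases == 9000
        assert row.breadth == pytest.approx(0.9)
        assert not row.fully_phased

    def test_full_block(self):
        core = {"G": GenomicInterval("chr1", 1000, 2000)}
        blocks = [rm.PhaseBlock("chr1", GenomicInterval("chr1", 0, 5000), 1)]
        row = rm.phase_breadth(blocks, core).row("G")
        assert row.breadth == 1.0 and row.fully_phased

    def test_overlapping_blocks_count_once(self):
        core = {"G": GenomicInterval("chr1", 0, 1000)}
        blocks = [
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 0, 600), 1),
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 400, 800), 2),
        ]
        row = rm.phase_breadth(blocks, core).row("G")
        # per-base boolean oracle
        covered = set()
        for b in blocks:
            covered.update(range(b.interval.start, b.interval.end))
        expected = len(covered & set(range(0, 1000)))
        assert row.phased_bases == expected

    def test_split_invariance(self):
        core = {"G": GenomicInterval("chr1", 100, 900)}
        whole = [rm.PhaseBlock("chr1", GenomicInterval("chr1", 50, 700), 1)]
        split = [
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 50, 400), 1),
            rm.PhaseBlock("chr1", GenomicInterval("chr1", 400, 700), 2),
        ]
        assert (
            rm.phase_breadth(whole, core).row("G").breadth
            == rm.phase_breadth(split, core).row("G").breadth
        )

    def test_zero_length_core_error(self):
        with pytest.raises(ValueError):
            rm.phase_breadth([], {"G": _FakeZero()})

    def test_summary_fields(self):
        cores = {
            f"G{i}": GenomicInterval("chr1", i * 1000, i * 1000 + 100)
            for i in range(4)
        }
        blocks = [rm.PhaseBlock("chr1", GenomicInterval("chr1", 0, 1150), 1)]
        s = rm.phase_breadth(blocks, cores).summary()
        assert set(s) == {"mean", "median", "q1", "q3", "fraction_fully_phased"}
        assert s["fraction_fully_phased"] == pytest.approx(0.5)


class _FakeZero:
    chrom = "chr1"
    length = 0


class TestBlocksFromPhasedVcf:
    CHROMS = {"chr1": 1_000_000}

    def _write(self, tmp_path, records):
        path = tmp_path / "p.vcf"
        write_vcf(records, self.CHROMS, path)
        return path

    def test_two_phased_hets(self, tmp_path):
        recs = [
            VcfRecord("chr1", 101, "v1", "A", "G", (1, 0), True, 77),
            VcfRecord("chr1", 500, "v2", "A", "G", (0, 1), True, 77),
        ]
        blocks, missing = rm.blocks_from_phased_vcf(self._write(tmp_path, recs))
        assert missing == 0
        (block,) = blocks
        # half-open block spans from first variant to end of last ref allele
        assert block.interval == GenomicInterval("chr1", 100, 500)
        assert block.phase_set == 77

    def test_single_variant_block(self, tmp_path):
        recs = [VcfRecord("chr1", 250, "v", "AT", "A", (1, 0), True, 9)]
        blocks, _ = rm.blocks_from_phased_vcf(self._write(tmp_path, recs))
        assert blocks[0].interval == GenomicInterval("chr1", 249, 251)

    def test_all_unphased_empty(self, tmp_path):
        recs = [
            VcfRecord("chr1", 101, "v1", "A", "G", (1, 0), False, None),
            VcfRecord("chr1", 500, "v2", "A", "G", (0, 1), False, None),
        ]
        blocks, _ = rm.blocks_from_phased_vcf(self._write(tmp_path, recs))
        assert blocks == []

    def test_phased_without_ps_counted(self, tmp_path):
        recs = [
            VcfRecord("chr1", 101, "v1", "A", "G", (1, 0), True, None),
            VcfRecord("chr1", 200, "v2", "A", "G", (1, 0), True, 5),
            VcfRecord("chr1", 300, "v3", "A", "G", (0, 1), True, 5),
        ]
        blocks, missing = rm.blocks_from_phased_vcf(self._write(tmp_path, recs))
        assert missing == 1
        assert len(blocks) == 1


class TestTimeToPhase:
    VARS = [("chr1", 10_000), ("chr1", 60_000)]

    def test_event_ordering(self):
        records = [
            make_record(
                read_id="a", start=5000, end=15_000, start_time=1200.0,
                haplotype=1, phase_set=7,
            ),
            make_record(
                read_id="b", start=55_000, end=65_000, start_time=3600.0,
                haplotype=2, phase_set=7,
            ),
        ]
        res = rm.time_to_phase(records, self.VARS)
        assert res.seconds == 3600.0

    def test_unlinked_phase_sets_undefined(self):
        records = [
            make_record(
                read_id="a", start=5000, end=15_000, start_time=100.0,
                haplotype=1, phase_set=7,
            ),
            make_record(
                read_id="b", start=55_000, end=65_000, start_time=200.0,
                haplotype=1, phase_set=8,
            ),
        ]
        assert rm.time_to_phase(records, self.VARS).seconds is None

    def test_min_support_two_unmet(self):
        records = [
            make_record(
                read_id="a", start=5000, end=65_000, start_time=100.0,
                haplotype=1, phase_set=7,
            ),
        ]
        assert rm.time_to_phase(records, self.VARS, min_support=2).seconds is None

    def test_single_spanning_read_links_both(self):
        records = [
            make_record(
                read_id="a", start=5000, end=65_000, start_time=500.0,
                haplotype=1, phase_set=3,
            ),
        ]
        assert rm.time_to_phase(records, self.VARS).seconds == 500.0

    def test_untimed_records_counted(self):
        records = [
            make_record(read_id="a", start=0, end=100, haplotype=1, phase_set=1),
        ]
        res = rm.time_to_phase(records, self.VARS)
        assert res.n_without_timestamp == 1

    def test_monotone_in_records(self):
        base = [
            make_record(
                read_id="a", start=5000, end=15_000, start_time=1000.0,
                haplotype=1, phase_set=7,
            ),
            make_record(
                read_id="b", start=55_000, end=65_000, start_time=8000.0,
                haplotype=2, phase_set=7,
            ),
        ]
        extra = base + [
            make_record(
                read_id="c", start=5000, end=65_000, start_time=2000.0,
                haplotype=1, phase_set=7,
            ),
        ]
        t1 = rm.time_to_phase(base, self.VARS).seconds
        t2 = rm.time_to_phase(extra, self.VARS).seconds
        assert t2 <= t1


def test_blocks_from_records():
    records = [
        make_record(read_id="a", start=100, end=500, haplotype=1, phase_set=3),
        make_record(read_id="b", start=400, end=900, haplotype=2, phase_set=3),
        make_record(read_id="c", start=2000, end=2500, haplotype=1, phase_set=4),
        make_record(read_id="d", start=0, end=50),  # untagged, ignored
    ]
    blocks = rm.blocks_from_records(records)
    assert [(b.phase_set, b.interval.start, b.interval.end) for b in blocks] == [
        (3, 100, 900),
        (4, 2000, 2500),
    ]
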