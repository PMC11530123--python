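"""Pre-built toy scenarios shared by the test suite and the CLI.

The default scenario is 2 x 1 Mb chromosomes with 10 target loci and one
planted duplication: the full target interval of one locus is copied to an
off-panel location, which starves that locus of primary alignments and
plants the supplementary-read signature the targeting QC diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval
from .panel_design import TargetPanel, build_targets
from .synthetic_fixtures import (
    DuplicationPair,
    RunParams,
    SimulationTruth,
    make_reference,
    simulate_run,
)

DEFAULT_SEED = 17
DUP_LOCUS = "G03"

CHROM_LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000}
SCENARIO_FLANK = 5_000

_GENES = [
    ("chr1", 60_000, 100_000, "G01"),
    ("chr1", 150_000, 180_000, "G02"),
    ("chr1", 230_000, 290_000, "G03"),
    ("chr1", 340_000, 370_000, "G04"),
    ("chr1", 430_000, 480_000, "G05"),
    ("chr2", 50_000, 90_000, "G06"),
    ("chr2", 140_000, 170_000, "G07"),
    ("chr2", 220_000, 280_000, "G08"),
    ("chr2", 330_000, 360_000, "G09"),
    ("chr2", 420_000, 470_000, "G10"),
]

HYPO_INTERVAL = GenomicInterval("chr1", 62_000, 65_000, "hypo_promoter")


@dataclass
class Scenario:
    reference: dict[str, str]
    panel: TargetPanel
    params: RunParams
    duplications: list[DuplicationPair]
    truth: SimulationTruth
    seed: int


def scenario_panel(flank: int = SCENARIO_FLANK) -> TargetPanel:
    genes = [GenomicInterval(c, s, e, n) for c, s, e, n in _GENES]
    return build_targets(genes, flank=flank, chrom_lengths=CHROM_LENGTHS)


def default_duplication(panel: TargetPanel) -> DuplicationPair:
    source = panel.locus(DUP_LOCUS).target
    return DuplicationPair(
        source=GenomicInterval(source.chrom, source.start, source.end, "dup_source"),
        copy=GenomicInterval(
            "chr2", 700_000, 700_000 + source.length, "dup_copy"
        ),
        identity=0.95,
    )


def default_scenario(
    seed: int = DEFAULT_SEED,
    with_duplication: bool = True,
    target_depth: float = 25.0,
    background_depth: float = 1.5,
    reference: Optional[dict[str, str]] = None,
) -> Scenario:
    """Build the reference and simulate one run; truth is fully seeded."""
    panel = scenario_panel()
    dups = [default_duplication(panel)] if with_duplication else []
    if reference is None:
        reference, _ = make_reference(CHROM_LENGTHS, dups, seed=seed)
    params = RunParams(target_depth=target_depth, background_depth=background_depth)
    records, truth = simulate_run(
        reference, panel, params=params, duplications=dups, seed=seed
    )
    scenario = Scenario(
        reference=reference,
        panel=panel,
        params=params,
        duplications=dups,
        truth=truth,
        seed=seed,
    )
    scenario.records = records  # type: ignore[attr-defined]
    return scenario
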