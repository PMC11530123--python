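# panelkit

Toolkit for targeted long-read (nanopore adaptive-sampling) panel
sequencing: design flanked target panels, assess targeting fidelity against
a reference, hard-mask duplicate regions that break targeting, and compute
run-level statistics — enrichment, phase breadth, time-to-phase, cis/trans
allelic architecture and hypomethylation clusters — from channel-labeled,
haplotagged long-read alignments.

## What it does

- **panel_design** — build a target panel from gene intervals with a
  configurable flank (default 50 kb per side), clip to chromosome bounds,
  merge overlaps, and compute each locus's expected share of targeted bases.
- **alignment_core** — alignment record model, the standard read filters
  (primary, non-duplicate, MAPQ ≥ 50 by default) and per-base coverage
  primitives.
- **targeting_qc** — regress log10 observed base fraction per locus on
  log10 expected fraction, flag under-targeted loci (one-sided studentized
  residual), diagnose duplicate regions from excess supplementary
  alignments, and emit a hard-mask interval set.
- **reference_masking** — produce and verify a hard-masked ('N') reference
  FASTA from a mask set.
- **run_metrics** — adaptive vs nonadaptive channel partitioning, per-locus
  and mean target coverage, background coverage from 10-kb windows clear of
  all targets, fold enrichment, phase breadth over strict gene boundaries,
  and post hoc time-to-phase.
- **haplotype_reporting** — cis/trans classification of phased variant
  pairs, variant distances and SV breakpoint spans from phased VCFs.
- **methylation_profile** — per-site 5mC aggregation and focal
  hypomethylated cluster detection.
- **synthetic_fixtures** — deterministic generators for toy references
  (with planted segmental duplications), adaptive-sampling runs, phased
  variants and methylomes with known ground truth; all tests run from these
  seeded fixtures, no downloads.

## CLI

All functionality is exposed through the `panelkit` command:

```sh
# generate a complete synthetic fixture set with ground truth
panelkit simulate --seed 17 --out-dir fixtures/

# build a flanked target panel
panelkit design --genes genes.bed --flank 50000 \
    --chrom-sizes ref.fa.fai --out targets.bed

# targeting QC: regression, flags, proposed mask
panelkit assess --sam fixtures/run.sam --targets fixtures/targets.bed \
    --uniqueness-mapq 1 --z 2.0 --out-dir qc/

# hard-mask the reference at the proposed intervals
panelkit mask --ref fixtures/reference.fa --mask qc/mask.bed \
    --out reference.masked.fa

# enrichment + phase breadth for one run
panelkit metrics --sam fixtures/run.sam --targets fixtures/targets.bed \
    --cores fixtures/cores.bed --phased-vcf fixtures/phased.vcf \
    --channels fixtures/channels.json --out-dir metrics/

# cis/trans architecture of variant pairs
panelkit phase-report --vcf fixtures/phased.vcf --pairs pairs.tsv \
    --out report.tsv

# hypomethylated cluster detection
panelkit methyl --calls fixtures/calls.bedmethyl \
    --regions fixtures/cores.bed --out-dir methyl/
```

## Acceptance

Acceptance is property-based (planted-truth recovery, oracle equivalence,
conservation identities, determinism) and lives in
`tests/test_acceptance.py`. The report script runs an end-to-end smoke
check of the planted-duplication pipeline and writes the (empty) numeric
target map:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Conventions

- Coordinates are 0-based half-open everywhere internally (BED-native);
  VCF positions are converted at the I/O boundary and reports print
  1-based.
- SAM tags: channel `ch`, run-relative start time in seconds `st`,
  haplotype `HP`, phase set `PS` — all tolerated as absent.
- Hard-masking uses uppercase 'N' and fixed 60-column FASTA wrapping so
  outputs are byte-deterministic.
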