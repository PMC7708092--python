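# biobank

A patient-centric analysis information management engine — the core of a
*digital biobank*. It tracks individuals, samples, aliquots, experiments and
projects in a validated, version-controlled metadata registry; imports raw
data into a checksummed, write-locked data lake; deploys versioned,
genome-assembly-aware applications over target/reference experiment tuples
with automatic deduplication; and automates downstream work through
status-driven signals and gated project/individual-level result merging.

## Who this is for

Groups running many bioinformatics pipelines over growing cohorts, who need
the bookkeeping around the pipelines — not the pipelines themselves — to be
systematic: which experiment belongs to which patient, where its files live
and whether they are intact, which tool version produced which result under
which configuration, and what still needs to run. The package is agnostic to
the analytical tools; applications wrap external commands and are registered
as plain Python objects.

## The model in brief

- **Metadata registry.** Records form an individual-centric relational
  model: `individual → sample → (aliquot) → experiment`, with experiments
  grouped into projects and annotated by technique and platform. Every write
  is validated (types, references, declared custom fields) and appended to
  an immutable audit trail of full snapshots; any previous version can be
  recovered, and recovery itself is a new audited version. Records with
  dependents cannot be deleted.
- **Analyses as first-class records.** An *analysis* is one run of an
  application — identified by `(name, version, assembly)` — on one canonical
  tuple of target and reference experiments (e.g. a tumor/normal pair). At
  most one non-superseded analysis exists per (identity, tuple): re-running
  is free and idempotent. Each analysis freezes its configuration (settings
  and reference-asset checksums) at creation and moves through the lifecycle
  `CREATED → STAGED → SUBMITTED → STARTED → SUCCEEDED | FAILED` (with
  `FAILED → STAGED` as the manual retry).
- **Data lake.** Files are matched to experiments by filename, moved or
  symlinked into a sharded layout (`<root>/<kind>/AA/BB/<key>`), SHA-256
  checksummed, and stripped of write permissions. Reference assets (genome
  FASTA, BED files) are registered by `(scope, key)`.
- **Automations.** Signals fire on status transitions (e.g. deploy QC on
  import; deploy downstream apps on QC success). The auto-merge aggregates
  all succeeded analyses of an application per project or individual, gated
  so it runs only when at least one analysis succeeded and none are still in
  flight, and never twice on an unchanged set. Superseded outputs (bug-fix
  version upgrades, re-merges) are archived to time-stamped `__legacy__`
  directories and remain retrievable.

## Worked example

```python
from biobank import Biobank, LocalExecutor
from biobank.fixtures import (CohortSpec, install_toy_apps, make_cohort,
                              make_raw_files)

bank = Biobank(lake_root="lake")
project = bank.get_or_create_project("P1")

# 3 individuals, one tumor + one normal experiment each
cohort = make_cohort(bank.store, CohortSpec(3, paired=True, seed=1), project)
deposit = make_raw_files(cohort.experiments, "deposit", reads_per_file=20,
                         seed=1)
scan = bank.lake.scan_and_match(deposit, cohort.experiments)
assets = bank.lake.import_data(scan, actor="admin")
print(len(assets), "files imported")

apps = install_toy_apps(bank.apps)          # toy GC-content QC app etc.
gc = apps["gc_qc"]
plan = bank.apps.plan_tuples(gc, cohort.experiments, "SINGLE_TARGET")
report = bank.apps.run(gc, plan.tuples, LocalExecutor())
bank.apps.wait()
for analysis in sorted(
        bank.db.all("analysis"),
        key=lambda a: bank.db.get("experiment", a["targets"][0])["custom_id"]):
    target = bank.db.get("experiment", analysis["targets"][0])["custom_id"]
    print(target, analysis["status"], analysis["results"])
```

prints

```
12 files imported
E-0001-N SUCCEEDED {'gc_fraction': 0.509}
E-0001-T SUCCEEDED {'gc_fraction': 0.511}
E-0002-N SUCCEEDED {'gc_fraction': 0.499}
E-0002-T SUCCEEDED {'gc_fraction': 0.513}
E-0003-N SUCCEEDED {'gc_fraction': 0.504}
E-0003-T SUCCEEDED {'gc_fraction': 0.484}
```

— one analysis per experiment; `gc_fraction` is the fraction of G/C bases
in that experiment's FASTQ files (≈0.5 for uniform random reads). Calling
`bank.apps.run(...)` again creates and submits nothing: all six analyses
are deduplicated.

The same operations are available from the shell (see `biobank --help`):
`register-batch`, `import-data`, `run-app`, `get-results`,
`sync-project-dirs`, `history`, `recover`, and friends, configured by a
single YAML file.

## Layout

```
src/biobank/
  metadata.py       validated CRUD, audit trail, queries, batch registration
  permissions.py    role-based authorization + per-user overrides
  datalake.py       scan/match, checksummed import, reference assets
  applications.py   app registry, tuple planning, dedup, lifecycle, supersession
  executors.py      local subprocess executor + recording test stub
  automations.py    signals, gated auto-merge, tick-driven scheduler
  fixtures.py       synthetic cohorts, FASTQ generation, toy applications
  toyjobs.py        the toy pipeline executables (run via the executor seam)
  cli.py, config.py, core.py, db.py, schema.py, errors.py
docs/methods.md     design and modelling notes
```
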