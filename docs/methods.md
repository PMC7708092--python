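# Methods and design notes

This note records the data model, the behavioural contracts, and the design
choices made where more than one reasonable implementation existed. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Metadata model

Entities are `individual`, `sample`, `aliquot`, `experiment`, `project`,
`technique`, `platform`, `disease`, `user`, plus the machine-managed
`data_asset`, `reference_asset`, `analysis`, `application`, and
`schema_extension`. Every record carries two identifiers:

- `system_id` — a UUID4 string, globally unique, immutable for the record's
  lifetime; the only key other records reference.
- `custom_id` — a human-friendly identifier. If absent at creation it is
  produced from a configurable template, by default
  `"{prefix}-{counter:04d}"` with a per-kind prefix (`I-0001`, `S-0001`,
  `E-0001`, …). Uniqueness is scoped to `(center, species)` for individuals
  (two centers may both have a patient "P-17") and global per kind for
  samples, aliquots and experiments, because batch deduplication and raw
  file matching key on the experiment/sample `custom_id`.

Validation happens in the application layer rather than as database
constraints: custom fields are declared at run time (`schema_extension`
records restricted to number/boolean/text), and the same declarative
field-spec table drives creation, update, batch ingestion, and query-path
validation. Persistence is a single embedded sqlite file with the field map
stored as JSON per row; at metadata scale (thousands of records, not
millions) full-table scans for uniqueness and reference checks are
deliberately simple and fast enough.

**Aliquots.** The aliquot is an optional pass-through level between sample
and experiment. The stored experiment always carries its sample: when an
experiment is created via an aliquot, the sample is derived from (or checked
against) the aliquot's sample, so downstream code never needs two lookup
paths. An experiment whose explicit sample disagrees with its aliquot's
sample is rejected.

## Audit trail and recovery

Every mutating call appends one audit row containing the complete
post-change snapshot (not a diff): recovery is then a single read, at the
cost of storing `O(fields)` per version — negligible at metadata scale.
Invariants:

- versions per entity are exactly `1..n`, timestamps strictly increasing
  (equal-clock writes are nudged by 1 µs);
- audit rows are never updated or deleted, and survive deletion of the
  record they snapshot;
- `recover_state(v)` *appends* a new version whose content equals the
  version-`v` snapshot — history never rewinds, so the trail remains a
  faithful log of what the record looked like at every moment, including
  during recoveries;
- a no-op update (empty change set, or changes equal to current state)
  writes no version.

Deletion is refused while any record references the target, with the full
list of referents in the error; the rule is applied uniformly to all kinds
(the protective behaviour is only strictly needed for samples, but a
uniform rule is easier to reason about and test).

## Permissions

Three additive roles: MANAGER (register metadata), ANALYST (run analyses),
ENGINEER (both, plus project editing). Data import and ownership are
reserved to a single designated admin account created at store setup.
Per-user overrides extend grants and are audited like any metadata change.
EDIT_PROJECT is additionally granted to a project's stakeholders.
Authentication is out of scope: callers supply a trusted username, as when
the CLI runs behind institutional login. Authorization is a pure function
of (roles, overrides, admin flag, action), asserted as the full 3×4 matrix
in the tests.

## Data lake

Storage paths are `lake_root/<kind>/<AA>/<BB>/<zero-padded key>` where
AA/BB are the first two digit-pairs of the key zero-padded to at least six
digits. This bounds fan-out to 100 entries per directory level (keys up to
10^6 per kind before a level widens) while keeping paths computable from
the key alone — no directory listing or database round-trip needed.

File→experiment matching is substring-of-`custom_id` plus exactly one
file-type regex (configurable; defaults cover FASTQ R1/R2, BAM, CRAM,
images, tables). A file whose name contains the IDs of two experiments
aborts the scan rather than guessing — with multiplexed deposits a wrong
silent assignment is far costlier than a re-run after renaming. Unmatched
files are reported, never silently imported.

Import stages each file (copy → SHA-256 verify → atomic rename → clear all
write bits), registers the asset, and only then removes the source in MOVE
mode; a failure mid-copy therefore leaves the source intact and nothing
registered. SYMLINK mode links the lake path to the source and locks the
source. SHA-256 was chosen as the checksum: collision-resistant, universally
available, fast enough for sequencing-scale files. Ownership transfer to
the admin account is recorded as metadata rather than performed with
privileged system calls, since chown semantics are unavailable to an
unprivileged test process; write-bit clearing is the enforced part.

## Applications and analyses

An application's identity is `(name, version, assembly)` — assembly-aware,
because outputs produced against different genome builds must never be
merged or compared. Registration requires `build_command` and
`parse_results` hooks; `validate_tuple` and the two merge hooks are
optional. Hook state lives in-process; identities are persisted, and a
fresh session re-attaching a persisted identity simply rehydrates it.

Tuple planning supports three designs: SINGLE_TARGET (one tuple per
experiment), PAIRED_BY_INDIVIDUAL (every tumor × every normal of the same
individual; unpairable experiments are returned with reasons, not dropped
silently), and TARGET_VS_POOL. Tuples are canonicalized by sorting each
side by `system_id`, so `[E1,E2]` and `[E2,E1]` address the same analysis.

Deduplication: at most one non-superseded analysis per (identity, canonical
tuple), enforced at `get_or_create_analysis`. The version is part of the
key deliberately — a corrected application version must be able to re-run
the same tuple. Settings are frozen into `config_snapshot` at creation
(together with the checksums of the reference assets in the application's
assembly scope); changing settings afterwards requires a version bump by
policy, keeping the snapshot an honest record of what ran.

Commands are shell strings written to `<storage>/head_job.sh` beside a
`settings.yaml` snapshot; the executor contract is `submit → handle`,
`poll → running|done(exit_code)`, reported done exactly once. The local
executor spawns child processes with logs under `logs/`; a recording stub
serves tests. `run(dry_run=True)` stops after staging: command on disk,
status STAGED, executor untouched. Previously succeeded or in-flight
analyses are never resubmitted; FAILED requires an explicit
`FAILED → STAGED` retry transition (no automatic retries — operators should
see failures).

On SUCCEEDED the results are parsed once against the declared results spec
(number/boolean/text scalars or verified-existing file paths) and the
output directory is write-locked. Supersession (same name and assembly,
strictly greater version) marks old analyses superseded, moves their
outputs into `<storage>/__legacy__/<UTC ISO-8601 µs timestamp>/`, and
creates fresh analyses under the new version; result resolution follows the
highest non-superseded version while legacy files remain readable in place.
Merge-level analyses are excluded from app supersession — the next re-merge
supersedes them through its own path.

## Automations

Signals run in registration order on every persisted status transition
(experiment import status and analysis lifecycle both dispatch). A raising
signal is caught, logged with restart instructions through a pluggable
notifier, and neither corrupts the triggering record's status nor blocks
later signals.

The merge gate: a merge of application A in scope S (project or individual)
runs iff at least one non-superseded analysis of A in S has SUCCEEDED and
none is in a non-terminal state (CREATED/STAGED/SUBMITTED/STARTED). FAILED
is terminal and does not block — otherwise one permanently failed analysis
would freeze a project's aggregation forever. Merges are evaluated
event-driven on every terminal transition rather than by polling; a merge
whose succeeded-input set equals the previous merge's inputs is a no-op, so
quiescent states merge at most once. Mutual exclusion per (application,
level, scope) uses a non-blocking in-process lock: a second concurrent
invocation no-ops (the in-flight merge, or the next terminal transition,
covers it). Individual-level merges span all of an individual's analyses
regardless of project. Merge outputs live under the scope's lake directory
(`.../merged/<app>/<version>/<key>/`) and are versioned and archived like
any other analysis.

The scheduler is tick-driven (no daemon thread): `tick()` runs each task at
most once per period, logging and surviving task exceptions. It exists as
the seam where periodic institutional syncs would attach; no cron or
long-running daemon is included.

## Synthetic data and toy applications

The fixtures module emulates the operational inputs of a sequencing-core
deployment, not the biology: cohorts of configurable size with one
tumor/normal experiment pair per individual (paired mode), batch tables in
CSV/TSV/XLSX, and gzip FASTQ deposits named `<experiment>_R{1,2}.fastq.gz`.
Reads are uniform-random ACGT of length 50 with constant quality —
realism is irrelevant because nothing downstream interprets base identity
beyond counting; what matters is that files are non-trivial, byte-exact
under a seed (gzip headers are pinned with `mtime=0`), and independently
checksummable. Consequently, passing tests demonstrate the correctness of
the bookkeeping machinery — matching, import integrity, dedup, lifecycle,
merging — and say nothing about any particular pipeline's scientific
output, which is by design out of scope.

The toy applications (GC fraction, read count, paired read-count
difference) are pure functions of their input files, invoked through
`python -m biobank.toyjobs …` via the real command/executor seam — never
in-process — so staging, submission, log capture, result parsing and
locking are genuinely exercised. Default problem sizes in the tests and the
acceptance script (cohorts of 5–100 experiments, 1–25 reads per file) are
chosen as the smallest sizes at which the contracts under test are
non-degenerate: dedup over 50 tuples, 20-file import, 10-analysis
supersession, a 100-experiment batch-to-project-directory run.

## Numerical and degenerate-input choices

- Timestamps: audit uses wall-clock floats with a 1 µs monotonic nudge;
  legacy directories use UTC ISO-8601 with microseconds, so mass
  supersession yields distinct directory names.
- Version comparison extracts integer runs from the version string
  (`1.0.10 > 1.0.9`); non-numeric schemes are rejected.
- Empty batch tables, empty deposit directories, empty projects, missing
  storage directories (usage = 0), and individuals without samples are all
  defined no-op/identity cases, tested as such.
- Query ordering is by `system_id`, making results deterministic across
  runs and equal to the brute-force scan oracle used in tests.
- sqlite runs in autocommit with savepoint-scoped per-row transactions for
  batch ingestion (a bad row rolls back its own writes only), and the
  connection is shared across threads (serialized threading mode) to honor
  the merge mutual-exclusion contract.

## Known limitations

- No HTTP API, web UI, or authentication; single-process, single-writer
  embedded database — the design seam for a client/server deployment is the
  `MetadataStore` interface, not a wire protocol.
- Cloud object stores are out of scope; the path-based storage contract is
  the attachment point.
- The executor ships with LOCAL capability only; cluster schedulers would
  implement the same two-method contract.
- Unix ownership transfer is recorded, not performed (requires privilege);
  write-locking is the enforced immutability mechanism, and root processes
  can bypass permission bits by definition.
- Schema migrations of the embedded database are out of scope.
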