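"""Deterministic synthetic cohorts, FASTQ files, and toy applications.

Everything every other module needs for testing is generated here with no
downloads: batch tables, registered cohorts, gzip FASTQ deposits (byte
identical under a fixed seed), and three toy applications (GC fraction,
read count, paired read-count difference) wired through the real
command/executor seam.
"""

from __future__ import annotations

import gzip
import random
import shlex
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .applications import ApplicationDescriptor, AppRegistry, ResultSpec
from .metadata import MetadataStore

READ_LENGTH = 50
QUALITY = "I" * READ_LENGTH


@dataclass
class CohortSpec:
    n_individuals: int
    samples_per_individual: int = 1
    paired: bool = False            # emit one TUMOR + one NORMAL per individual
    techniques: list[str] = dc_field(default_factory=lambda: ["WGS"])
    species: str = "HUMAN"
    center: str = "MSK"
    seed: int = 0


@dataclass
class Cohort:
    individuals: list[dict] = dc_field(default_factory=list)
    samples: list[dict] = dc_field(default_factory=list)
    experiments: list[dict] = dc_field(default_factory=list)


def cohort_rows(spec: CohortSpec) -> list[dict]:
    """Batch-table rows for a synthetic cohort; fully seed-deterministic."""
    rng = random.Random(spec.seed)
    rows = []
    for i in range(1, spec.n_individuals + 1):
        ind = f"I-{i:04d}"
        sex = rng.choice(["MALE", "FEMALE"])
        technique = spec.techniques[(i - 1) % len(spec.techniques)]
        if spec.paired:
            branches = [("T", "TUMOR"), ("N", "NORMAL")]
        else:
            branches = [(str(j), "TUMOR")
                        for j in range(1, spec.samples_per_individual + 1)]
        for tag, sample_class in branches:
            rows.append({
                "individual_id": ind,
                "sample_id": f"S-{i:04d}-{tag}",
                "experiment_id": f"E-{i:04d}-{tag}",
                "technique": technique,
                "platform": "NovaSeq",
                "species": spec.species,
                "center": spec.center,
                "sex": sex,
                "sample_class": sample_class,
            })
    return rows


def write_batch_table(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(cohort_rows(spec))
    if path.suffix.lower() == ".csv":
        frame.to_csv(path, index=False)
    elif path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, sep="\t", index=False)
    return path


def make_cohort(store: MetadataStore, spec: CohortSpec, project: dict,
                actor: str = "admin") -> Cohort:
    """Register a synthetic cohort directly (no intermediate file)."""
    cohort = Cohort()
    for row in cohort_rows(spec):
        experiment = store._register_row(pd.Series(row), project, actor)
        cohort.experiments.append(experiment)
    seen_s: set[str] = set()
    seen_i: set[str] = set()
    for exp in cohort.experiments:
        sample = store.db.get("sample", exp["sample"])
        if sample["system_id"] not in seen_s:
            seen_s.add(sample["system_id"])
            cohort.samples.append(sample)
        if sample["individual"] not in seen_i:
            seen_i.add(sample["individual"])
            cohort.individuals.append(store.db.get("individual",
                                                   sample["individual"]))
    return cohort


# ------------------------------------------------------------ raw FASTQ files

def _random_read(rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(READ_LENGTH))


def write_fastq(path: str | Path, reads: list[str], name_prefix: str = "read"
                ) -> Path:
    """Write a gzip FASTQ; gzip header pinned (mtime=0, no filename) so the
    bytes depend only on the records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            for i, seq in enumerate(reads, 1):
                record = f"@{name_prefix}:{i}\n{seq}\n+\n{'I' * len(seq)}\n"
                gz.write(record.encode())
    return path


def make_raw_files(experiments: list[dict], out_dir: str | Path,
                   reads_per_file: int = 100, seed: int = 0) -> Path:
    """Emit paired R1/R2 FASTQ files named ``<custom_id>_R{1,2}.fastq.gz``
    into a deposit directory; deterministic under the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for exp in sorted(experiments, key=lambda e: e["custom_id"]):
        for mate in (1, 2):
            rng = random.Random(f"{seed}:{exp['custom_id']}:R{mate}")
            reads = [_random_read(rng) for _ in range(reads_per_file)]
            write_fastq(out_dir / f"{exp['custom_id']}_R{mate}.fastq.gz",
                        reads, name_prefix=f"{exp['custom_id']}:{mate}")
    return out_dir


# ------------------------------------------------------------ toy applications

def _result_path(outdir: str, filename: str) -> Path:
    return Path(outdir) / filename


def _read_kv(path: Path) -> dict[str, str]:
    out = {}
    for line in path.read_text().splitlines():
        key, _, value = line.partition("=")
        out[key] = value
    return out


def _all_paths(inputs: dict, group: str) -> list[str]:
    return [p for entry in inputs[group] for p in entry["paths"]]


def _merge_tsv(result_key: str):
    """Merge hook: one TSV row per input analysis."""

    def merge(app, analyses, outdir):
        path = Path(outdir) / "merged.tsv"
        with open(path, "w") as fh:
            fh.write(f"analysis\ttargets\t{result_key}\n")
            for rec in analyses:
                fh.write(f"{rec['system_id']}\t{','.join(rec['targets'])}\t"
                         f"{rec['results'].get(result_key)}\n")
        return {"merged_table": str(path)}

    return merge


def _gc_build(app, analysis, inputs):
    files = " ".join(shlex.quote(p) for p in _all_paths(inputs, "targets"))
    return (f"{shlex.quote(sys.executable)} -m biobank.toyjobs gc-qc {files} "
            f"--out {shlex.quote(inputs['outdir'])}")


def _gc_parse(app, analysis, outdir):
    values = _read_kv(_result_path(outdir, "gc_qc.txt"))
    return {"gc_fraction": float(values["gc_fraction"])}


def _count_build(app, analysis, inputs):
    files = " ".join(shlex.quote(p) for p in _all_paths(inputs, "targets"))
    return (f"{shlex.quote(sys.executable)} -m biobank.toyjobs read-count "
            f"{files} --out {shlex.quote(inputs['outdir'])}")


def _count_parse(app, analysis, outdir):
    values = _read_kv(_result_path(outdir, "read_count.txt"))
    return {"n_reads": int(values["n_reads"])}


def _diff_build(app, analysis, inputs):
    targets = " ".join(shlex.quote(p) for p in _all_paths(inputs, "targets"))
    refs = " ".join(shlex.quote(p) for p in _all_paths(inputs, "references"))
    return (f"{shlex.quote(sys.executable)} -m biobank.toyjobs paired-diff "
            f"--targets {targets} --references {refs} "
            f"--out {shlex.quote(inputs['outdir'])}")


def _diff_parse(app, analysis, outdir):
    values = _read_kv(_result_path(outdir, "paired_diff.txt"))
    return {"delta_reads": int(values["delta_reads"])}


def gc_qc_descriptor(version: str = "1.0.0") -> ApplicationDescriptor:
    return ApplicationDescriptor(
        name="gc_qc", version=version, assembly=None,
        results_spec={"gc_fraction": ResultSpec("number")},
        build_command=_gc_build, parse_results=_gc_parse,
        merge_project=_merge_tsv("gc_fraction"),
        merge_individual=_merge_tsv("gc_fraction"),
    )


def read_count_descriptor(version: str = "1.0.0") -> ApplicationDescriptor:
    return ApplicationDescriptor(
        name="read_count", version=version, assembly=None,
        results_spec={"n_reads": ResultSpec("number")},
        build_command=_count_build, parse_results=_count_parse,
        merge_project=_merge_tsv("n_reads"),
        merge_individual=_merge_tsv("n_reads"),
    )


def paired_diff_descriptor(version: str = "1.0.0") -> ApplicationDescriptor:
    return ApplicationDescriptor(
        name="paired_diff", version=version, assembly=None,
        results_spec={"delta_reads": ResultSpec("number")},
        build_command=_diff_build, parse_results=_diff_parse,
        merge_project=_merge_tsv("delta_reads"),
        merge_individual=_merge_tsv("delta_reads"),
    )


def install_toy_apps(target) -> dict[str, ApplicationDescriptor]:
    """Register the toy applications (GC_QC 1.0.0 and 1.0.1, READ_COUNT,
    PAIRED_DIFF) on an :class:`AppRegistry` (or anything exposing ``.apps``)."""
    registry: AppRegistry = getattr(target, "apps", target)
    apps = {
        "gc_qc": gc_qc_descriptor("1.0.0"),
        "gc_qc_fixed": gc_qc_descriptor("1.0.1"),
        "read_count": read_count_descriptor("1.0.0"),
        "paired_diff": paired_diff_descriptor("1.0.0"),
    }
    for app in apps.values():
        registry.register_application(app)
    return apps
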