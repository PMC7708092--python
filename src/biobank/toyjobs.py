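"""Toy pipeline executables (``python -m biobank.toyjobs ...``).

These are the external "tools" the toy applications wrap.  They are invoked
through the real command-string + executor seam — never in-process — so
tests exercise the same staging/submission path a production pipeline would.
Each subcommand reads FASTQ files and writes one ``key=value`` result file
into the output directory.
"""

from __future__ import annotations

import argparse
import gzip
import sys
from pathlib import Path


def read_sequences(path: str | Path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        lines = [line.rstrip("\n") for line in handle]
    return [lines[i] for i in range(1, len(lines), 4)]


def gc_fraction(files: list[str]) -> float:
    gc = total = 0
    for path in files:
        for seq in read_sequences(path):
            gc += sum(base in "GCgc" for base in seq)
            total += len(seq)
    return gc / total if total else 0.0


def count_reads(files: list[str]) -> int:
    return sum(len(read_sequences(path)) for path in files)


def _write(outdir: str, name: str, **values) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / name, "w") as fh:
        for key, value in values.items():
            fh.write(f"{key}={value}\n")


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(prog="biobank.toyjobs")
    sub = parser.add_subparsers(dest="command", required=True)

    p = sub.add_parser("gc-qc")
    p.add_argument("files", nargs="+")
    p.add_argument("--out", required=True)

    p = sub.add_parser("read-count")
    p.add_argument("files", nargs="+")
    p.add_argument("--out", required=True)

    p = sub.add_parser("paired-diff")
    p.add_argument("--targets", nargs="+", required=True)
    p.add_argument("--references", nargs="+", required=True)
    p.add_argument("--out", required=True)

    args = parser.parse_args(argv)
    if args.command == "gc-qc":
        _write(args.out, "gc_qc.txt", gc_fraction=gc_fraction(args.files))
    elif args.command == "read-count":
        _write(args.out, "read_count.txt", n_reads=count_reads(args.files))
    else:
        delta = count_reads(args.targets) - count_reads(args.references)
        _write(args.out, "paired_diff.txt", delta_reads=delta)
    return 0


if __name__ == "__main__":
    sys.exit(main())
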