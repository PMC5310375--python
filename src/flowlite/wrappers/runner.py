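"""Runtime behaviour shared by every packaged wrapper executable.

A wrapper is invoked in one of two modes:

* ``<wrapper> --requirements --files <n> [--param k=v ...]`` — print the
  module's resource requests as ``key: value`` lines and exit.

* ``<wrapper> --run_fn <run file> --job_id <id> --prev_job_id <id>
  --cores <n> --mem <bytes> [--param ...] [--ref type=path ...]`` — do the
  work: look up this job's input files in the run file, construct the tool
  command, execute it, and record results.

All structured communication is through the run file (START/DONE/FAIL
markers, output records) and through ``###CF*`` marker lines on stdout,
which land in the job log and are parsed by the reporting layer.  The
expected output filenames are exported in the ``CF_STUB_OUTPUTS``
environment variable while the tool runs; real tools never look at it, and
the stub toolbox uses it to create the declared outputs when testing
pipelines without any bioinformatics tools installed.
"""

from __future__ import annotations

import argparse
import os
import shlex
import subprocess
import sys
from pathlib import Path

from .. import runfile as rf
from . import generate_command, outputs_for
from .specs import BY_NAME


def _requirements_text(name: str) -> str:
    spec = BY_NAME[name]
    lines = [
        f"cores: {spec.cores}",
        f"memory: {spec.memory}",
        f"time: {spec.time}",
    ]
    if spec.time_per_file:
        lines.append("time_per_file: true")
    if spec.required_ref_types:
        lines.append("references: " + " ".join(spec.required_ref_types))
    if spec.environment_modules:
        lines.append("modules: " + " ".join(spec.environment_modules))
    return "\n".join(lines) + "\n"


def _probe_version(spec, cwd: Path) -> str:
    if not spec.version_args:
        return "unknown"
    try:
        proc = subprocess.run(
            [spec.tool, *spec.version_args],
            capture_output=True, text=True, timeout=60, cwd=cwd,
        )
    except (OSError, subprocess.TimeoutExpired):
        return "unknown"
    for stream in (proc.stdout, proc.stderr):
        for line in stream.splitlines():
            if line.strip():
                return line.strip()
    return "unknown"


def main(name: str, argv: list[str] | None = None) -> int:
    if name not in BY_NAME:
        print(f"###CF_ERR unknown wrapper module: {name}", flush=True)
        return 1
    spec = BY_NAME[name]
    ap = argparse.ArgumentParser(prog=name, add_help=False)
    ap.add_argument("--requirements", action="store_true")
    ap.add_argument("--files", type=int, default=1)
    ap.add_argument("--param", action="append", default=[])
    ap.add_argument("--genome_id", default=None)
    ap.add_argument("--run_fn", default=None)
    ap.add_argument("--job_id", default=None)
    ap.add_argument("--prev_job_id", default=rf.START_SENTINEL)
    ap.add_argument("--cores", type=int, default=1)
    ap.add_argument("--mem", type=int, default=2**30)
    ap.add_argument("--ref", action="append", default=[])
    args = ap.parse_args(argv)

    if args.requirements:
        sys.stdout.write(_requirements_text(name))
        return 0

    if not args.run_fn or not args.job_id:
        print("###CF_ERR --run_fn and --job_id are required in run mode", flush=True)
        return 2

    run_fn = Path(args.run_fn)
    cwd = run_fn.parent
    rf.append_marker(run_fn, args.job_id, rf.MARK_START)
    print(f"###CF_START {args.job_id}", flush=True)
    try:
        rc = _run(spec, args, run_fn, cwd)
    except Exception as exc:  # any unexpected failure must be recorded
        print(f"###CF_ERR {name}: {exc}", flush=True)
        rc = 1
    if rc == 0:
        rf.append_marker(run_fn, args.job_id, rf.MARK_DONE)
    else:
        rf.append_marker(run_fn, args.job_id, rf.MARK_FAIL)
    print(f"###CF_END {args.job_id}", flush=True)
    return rc


def _run(spec, args, run_fn: Path, cwd: Path) -> int:
    from ..module_api import ResourceRequest

    inputs = rf.inputs_for(run_fn, args.prev_job_id)
    if not inputs:
        print(f"###CF_ERR {spec.name}: no input files recorded under job "
              f"{args.prev_job_id}", flush=True)
        return 1
    genome_paths = {}
    for ref in args.ref:
        ref_type, _, path = ref.partition("=")
        genome_paths[ref_type] = path
    granted = ResourceRequest(cores=max(1, args.cores), memory=max(1, args.mem))
    paired = len(inputs) == 2 and bool(spec.paired) and _looks_paired(inputs)
    commands = generate_command(
        spec,
        inputs if not paired else _as_paired(inputs),
        params=args.param,
        genome_paths=genome_paths,
        granted=granted,
    )
    outputs = outputs_for(spec, inputs)
    env = dict(os.environ)
    env["CF_STUB_OUTPUTS"] = os.pathsep.join(outputs)

    version = _probe_version(spec, cwd)
    print(f"###CF_VERS {spec.tool}:{version}", flush=True)

    for cmd in commands:
        print(f"###CFCMD {cmd}", flush=True)
        try:
            proc = subprocess.run(
                shlex.split(cmd), capture_output=True, text=True, cwd=cwd, env=env
            )
        except OSError as exc:
            print(f"###CF_ERR {spec.name}: cannot execute {spec.tool}: {exc}", flush=True)
            return 1
        if proc.stdout:
            sys.stdout.write(proc.stdout)
        if proc.stderr:
            sys.stdout.write(proc.stderr)
        sys.stdout.flush()
        if proc.returncode != 0:
            print(f"###CF_ERR {spec.name}: {spec.tool} exited {proc.returncode}", flush=True)
            return proc.returncode
    missing = [o for o in outputs if not (cwd / o).exists()]
    if missing:
        print(f"###CF_ERR {spec.name}: declared outputs missing: {', '.join(missing)}",
              flush=True)
        return 1
    for out in outputs:
        print(f"###CF_OUT {out}", flush=True)
    if outputs:
        rf.append_outputs(run_fn, args.job_id, outputs)
    return 0


def _looks_paired(inputs) -> bool:
    from ..helpers import group_paired_files

    try:
        groups = group_paired_files(list(inputs))
    except Exception:
        return False
    return len(groups) == 1 and groups[0].is_paired


def _as_paired(inputs):
    from ..helpers import group_paired_files

    groups = group_paired_files(list(inputs))
    return groups[0]
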