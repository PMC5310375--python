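"""Daemon-free pipeline state: the ``.run`` file.

One ``.run`` file per input group is the *only* state store for a run — no
monitoring process, no database.  Layout::

    /*
    @run_id fastq_bowtie2_20260927-120000_0
    @pipeline fastq_bowtie2
    @created 2026-09-27T12:00:00+00:00
    @genome GRCh38
    @cfg max_cores 8
    @job cf_..._fastqc_0 fastqc start_000
    #fastqc
    #trim_galore
    \t#bowtie2
    */
    start_000<TAB>sample_R1.fastq.gz
    start_000<TAB>sample_R2.fastq.gz
    cf_..._fastqc_0<TAB>###CF_START<TAB>2026-09-27T12:01:00+00:00
    cf_..._fastqc_0<TAB>###CF_DONE<TAB>2026-09-27T12:02:00+00:00

The header (between ``/*`` and ``*/``) is written once and never mutated;
the body is strictly append-only TSV.  Plain body lines record one output
file per finished step under its job id; the sentinel ``start_000`` owns
the initial inputs.  Marker lines (``###CF_START``/``###CF_DONE``/
``###CF_FAIL``) carry an ISO-8601 UTC timestamp as a third field so that
run status — including total duration — is a pure function of the file's
contents.
"""

from __future__ import annotations

import datetime as _dt
import fcntl
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .pipeline import JobPlan, Pipeline, render_pipeline

log = logging.getLogger(__name__)

START_SENTINEL = "start_000"
MARK_START = "###CF_START"
MARK_DONE = "###CF_DONE"
MARK_FAIL = "###CF_FAIL"


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).replace(microsecond=0).isoformat()


@dataclass
class RunHeader:
    run_id: str = ""
    pipeline_name: str = ""
    created: str = ""
    genome_id: str = ""
    config: dict[str, str] = field(default_factory=dict)
    jobs: list[tuple[str, str, str]] = field(default_factory=list)  # (job_id, module, upstream)
    pipeline_text: str = ""


@dataclass
class RunFileData:
    path: Path
    header: RunHeader
    body: list[tuple[str, ...]]  # split TSV fields, 2 or 3 per line


class RunFileError(Exception):
    pass


def create_runfiles(
    directory: str | os.PathLike,
    pipeline: Pipeline,
    plan: JobPlan,
    config_items: dict[str, str],
    input_groups: Sequence[Sequence[str]],
    run_id: str,
    genome_id: str | None = None,
) -> list[Path]:
    """Write one ``.run`` file per input group; never overwrites.

    Each file records only its own group's initial inputs under
    ``start_000`` plus the planned jobs for that group in the header.
    """
    directory = Path(directory)
    if not os.access(directory, os.W_OK):
        raise RunFileError(f"run directory not writable: {directory}")
    paths: list[Path] = []
    created = _utcnow()
    for group, files in enumerate(input_groups):
        base = directory / f"{pipeline.name}_{run_id}_{group}.run"
        path, k = base, 1
        while path.exists():
            path = directory / f"{pipeline.name}_{run_id}_{group}.{k}.run"
            k += 1
        group_jobs = [j for j in plan.jobs if j.group == group]
        lines = ["/*"]
        lines.append(f"@run_id {pipeline.name}_{run_id}_{group}")
        lines.append(f"@pipeline {pipeline.name}")
        lines.append(f"@created {created}")
        if genome_id:
            lines.append(f"@genome {genome_id}")
        for key, val in config_items.items():
            lines.append(f"@cfg {key} {val}")
        for j in group_jobs:
            lines.append(f"@job {j.name} {j.module_name} {j.upstream or START_SENTINEL}")
        lines.append(render_pipeline(pipeline).rstrip("\n"))
        lines.append("*/")
        for f in files:
            lines.append(f"{START_SENTINEL}\t{f}")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def parse_runfile(path: str | os.PathLike) -> RunFileData:
    """Parse header + body; tolerant of truncation (crash safety): any
    prefix of a valid file parses, with whatever records survived."""
    path = Path(path)
    header = RunHeader()
    body: list[tuple[str, ...]] = []
    in_header = False
    header_done = False
    pipeline_lines: list[str] = []
    try:
        text = path.read_text(errors="replace")
    except OSError as exc:
        raise RunFileError(f"cannot read run file {path}: {exc}") from exc
    for raw in text.splitlines():
        if not header_done:
            if raw.strip() == "/*":
                in_header = True
                continue
            if raw.strip() == "*/":
                in_header, header_done = False, True
                continue
            if in_header:
                if raw.startswith("@run_id "):
                    header.run_id = raw[8:].strip()
                elif raw.startswith("@pipeline "):
                    header.pipeline_name = raw[10:].strip()
                elif raw.startswith("@created "):
                    header.created = raw[9:].strip()
                elif raw.startswith("@genome "):
                    header.genome_id = raw[8:].strip()
                elif raw.startswith("@cfg "):
                    key, _, val = raw[5:].partition(" ")
                    header.config[key] = val
                elif raw.startswith("@job "):
                    parts = raw[5:].split()
                    if len(parts) == 3:
                        header.jobs.append((parts[0], parts[1], parts[2]))
                else:
                    pipeline_lines.append(raw)
                continue
            # text before any header block: ignore
            continue
        if not raw.strip():
            continue
        fields = tuple(raw.split("\t"))
        if len(fields) >= 2:
            body.append(fields)
        # a lone field is a truncated/garbled line: skip, stay parseable
    header.pipeline_text = "\n".join(pipeline_lines)
    return RunFileData(path=path, header=header, body=body)


def append_outputs(
    runfile: str | os.PathLike,
    job_id: str,
    filenames: Iterable[str],
    known_jobs: Iterable[str] | None = None,
) -> None:
    """Append output records atomically.

    The block is written with a single ``write()`` of complete lines under
    an advisory lock, so concurrent appenders from parallel branches never
    interleave partial lines.
    """
    if known_jobs is not None and job_id not in set(known_jobs) | {START_SENTINEL}:
        log.warning("run file %s: appending outputs for unplanned job %s", runfile, job_id)
    block = "".join(f"{job_id}\t{name}\n" for name in filenames)
    if not block:
        return
    with open(runfile, "a") as fh:
        fcntl.flock(fh, fcntl.LOCK_EX)
        try:
            fh.write(block)
            fh.flush()
        finally:
            fcntl.flock(fh, fcntl.LOCK_UN)


def append_marker(runfile: str | os.PathLike, job_id: str, marker: str, timestamp: str | None = None) -> None:
    """Record a job lifecycle event (START/DONE/FAIL) with a timestamp."""
    stamp = timestamp or _utcnow()
    with open(runfile, "a") as fh:
        fcntl.flock(fh, fcntl.LOCK_EX)
        try:
            fh.write(f"{job_id}\t{marker}\t{stamp}\n")
            fh.flush()
        finally:
            fcntl.flock(fh, fcntl.LOCK_UN)


def _is_marker(fields: tuple[str, ...]) -> bool:
    return len(fields) >= 2 and fields[1] in {MARK_START, MARK_DONE, MARK_FAIL}


def outputs_of(data: RunFileData, job_id: str) -> list[str]:
    return [f[1] for f in data.body if f[0] == job_id and not _is_marker(f)]


def inputs_for(runfile: str | os.PathLike | RunFileData, prev_job_id: str) -> list[str]:
    """Files recorded under *prev_job_id*, order preserved.

    A pass-through step (completed but emitted no outputs — QC-only
    modules) resolves transitively to its own upstream's files.
    """
    data = runfile if isinstance(runfile, RunFileData) else parse_runfile(runfile)
    upstream_of = {job_id: up for job_id, _module, up in data.header.jobs}
    seen: set[str] = set()
    job = prev_job_id
    while job not in seen:
        seen.add(job)
        files = outputs_of(data, job)
        if files:
            return files
        nxt = upstream_of.get(job)
        if nxt is None:
            return []
        job = nxt
    return []


# ---------------------------------------------------------------------------
# status derivation


@dataclass
class StepStatus:
    job_id: str
    module: str
    state: str  # queued | running | done | failed | skipped


@dataclass
class RunStatus:
    run_id: str
    pipeline: str
    working_dir: str
    steps: list[StepStatus]
    duration_seconds: float
    corrupt: bool = False

    @property
    def remaining(self) -> int:
        return sum(1 for s in self.steps if s.state in {"queued", "running"})

    @property
    def duration_human(self) -> str:
        return humanize_duration(self.duration_seconds)


def humanize_duration(seconds: float) -> str:
    seconds = int(max(0, seconds))
    days, rem = divmod(seconds, 86400)
    hours, rem = divmod(rem, 3600)
    minutes, secs = divmod(rem, 60)
    if days:
        return f"{days}d {hours}h"
    if hours:
        return f"{hours}h {minutes}m"
    if minutes:
        return f"{minutes}m {secs}s"
    return f"{secs}s"


def _parse_iso(text: str) -> _dt.datetime | None:
    try:
        t = _dt.datetime.fromisoformat(text)
    except ValueError:
        return None
    # a truncated timestamp can parse as naive; assume UTC
    return t if t.tzinfo else t.replace(tzinfo=_dt.timezone.utc)


def derive_status(data: RunFileData) -> RunStatus:
    """Per-step states from markers alone.

    done: DONE marker (or outputs recorded and no FAIL); failed: FAIL
    marker; running: START without DONE/FAIL; skipped: an ancestor failed;
    queued otherwise.  Duration = last timestamped event - header creation.
    """
    marks: dict[str, set[str]] = {}
    last_event: _dt.datetime | None = None
    for fields in data.body:
        if _is_marker(fields):
            marks.setdefault(fields[0], set()).add(fields[1])
            if len(fields) >= 3:
                t = _parse_iso(fields[2])
                if t is not None:
                    last_event = max(last_event, t) if last_event else t
    has_outputs = {f[0] for f in data.body if not _is_marker(f)}
    upstream_of = {job_id: up for job_id, _m, up in data.header.jobs}

    state: dict[str, str] = {}

    def failed_ancestor(job: str) -> bool:
        cur, seen = upstream_of.get(job), set()
        while cur and cur != START_SENTINEL and cur not in seen:
            seen.add(cur)
            if state.get(cur) in {"failed", "skipped"}:
                return True
            cur = upstream_of.get(cur)
        return False

    steps: list[StepStatus] = []
    for job_id, module, _up in data.header.jobs:
        m = marks.get(job_id, set())
        if MARK_FAIL in m:
            st = "failed"
        elif MARK_DONE in m or (job_id in has_outputs and MARK_START not in m):
            st = "done"
        elif MARK_START in m:
            st = "running"
        elif failed_ancestor(job_id):
            st = "skipped"
        else:
            st = "queued"
        state[job_id] = st
        steps.append(StepStatus(job_id=job_id, module=module, state=st))

    created = _parse_iso(data.header.created)
    if created and last_event:
        duration = (last_event - created).total_seconds()
    elif created:
        duration = (_dt.datetime.now(_dt.timezone.utc) - created).total_seconds()
    else:
        duration = 0.0
    return RunStatus(
        run_id=data.header.run_id,
        pipeline=data.header.pipeline_name,
        working_dir=str(data.path.parent),
        steps=steps,
        duration_seconds=duration,
    )


def status(search_dirs: Sequence[str | os.PathLike]) -> list[RunStatus]:
    """Scan directories for ``.run`` files; corrupt files are reported, not
    fatal, and the scan continues."""
    out: list[RunStatus] = []
    for d in search_dirs:
        d = Path(d)
        if not d.is_dir():
            continue
        for path in sorted(d.glob("*.run")):
            try:
                out.append(derive_status(parse_runfile(path)))
            except Exception as exc:  # pragma: no cover - defensive
                log.warning("corrupt run file %s: %s", path, exc)
                out.append(
                    RunStatus(
                        run_id=path.stem,
                        pipeline="?",
                        working_dir=str(path.parent),
                        steps=[],
                        duration_seconds=0.0,
                        corrupt=True,
                    )
                )
    return out


def format_status(statuses: Sequence[RunStatus]) -> str:
    """One block per run: id, directory, duration, per-step states."""
    if not statuses:
        return "No run files found.\n"
    blocks = []
    for st in statuses:
        lines = [f"== {st.run_id} ({st.pipeline})"]
        lines.append(f"   dir: {st.working_dir}")
        lines.append(f"   duration: {st.duration_human}   steps remaining: {st.remaining}")
        if st.corrupt:
            lines.append("   [corrupt run file]")
        for step in st.steps:
            lines.append(f"   {step.state:<8} {step.module} ({step.job_id})")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
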