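"""Backend-specific job submission with native dependency holds.

Three batch-scheduler dialects are supported plus a local serial executor:

============  ==========  =============================  =================
backend       submit      dependency hold                id extraction
============  ==========  =============================  =================
slurm         ``sbatch``  ``--dependency=afterok:<id>``  "Submitted batch job <id>"
gridengine    ``qsub``    ``-hold_jid <id>``             "Your job <id> (...)"
lsf           ``bsub``    ``-w "done(<id>)"``            "Job <id> is submitted"
============  ==========  =============================  =================

``afterok``/``done()`` semantics mean downstream jobs are cancelled when an
upstream job fails, matching the abort-on-error reporting model.  Memory
dialects: slurm ``--mem`` in MB, gridengine ``-l h_vmem=`` with a G suffix
per core, lsf ``-M`` in MB.

Submissions go through a single injectable command-runner seam so the
entire submission path is testable with scripted fakes and no scheduler.
Local mode runs each input group's jobs strictly in series (depth-first,
parent before children); a failure skips that job's descendants but leaves
other branches running.  There is no resource enforcement in local mode —
grants are passed through to wrappers but nothing polices them.
"""

from __future__ import annotations

import math
import re
import shlex
import subprocess
import sys
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

BACKENDS = ("slurm", "gridengine", "lsf", "local")


class SchedulerError(Exception):
    pass


@dataclass
class JobSpec:
    """One concrete scheduler job."""

    name: str
    command: str  # the module invocation, shell-quoted
    dependency: str | None = None  # upstream scheduler id
    cores: int = 1
    memory: int = 2**30  # bytes
    time: int = 60  # minutes
    queue: str | None = None
    project: str | None = None
    stdout_log: str = ""
    stderr_log: str = ""


def _mb(nbytes: int) -> int:
    return max(1, math.ceil(nbytes / 2**20))


def make_submit_command(backend: str, job: JobSpec) -> str:
    """Deterministic submission command line for one job."""
    if backend == "slurm":
        parts = ["sbatch", f"--job-name={job.name}", f"--cpus-per-task={job.cores}",
                 f"--mem={_mb(job.memory)}M", f"--time={job.time}"]
        if job.dependency:
            parts.append(f"--dependency=afterok:{job.dependency}")
        if job.queue:
            parts.append(f"--partition={job.queue}")
        if job.project:
            parts.append(f"--account={job.project}")
        if job.stdout_log:
            parts.append(f"--output={job.stdout_log}")
        if job.stderr_log:
            parts.append(f"--error={job.stderr_log}")
        parts.append(f"--wrap={shlex.quote(job.command)}")
        return " ".join(parts)
    if backend == "gridengine":
        # h_vmem is per-core on gridengine
        per_core_g = max(1, math.ceil(job.memory / job.cores / 2**30))
        parts = ["qsub", "-b", "y", "-cwd", "-V", "-N", job.name,
                 "-pe", "smp", str(job.cores), "-l", f"h_vmem={per_core_g}G"]
        if job.dependency:
            parts += ["-hold_jid", job.dependency]
        if job.queue:
            parts += ["-q", job.queue]
        if job.project:
            parts += ["-P", job.project]
        if job.stdout_log:
            parts += ["-o", job.stdout_log]
        if job.stderr_log:
            parts += ["-e", job.stderr_log]
        return " ".join(parts) + f" {job.command}"
    if backend == "lsf":
        parts = ["bsub", "-J", job.name, "-n", str(job.cores), "-M", str(_mb(job.memory)),
                 "-W", str(job.time)]
        if job.dependency:
            parts.append(f'-w "done({job.dependency})"')
        if job.queue:
            parts += ["-q", job.queue]
        if job.project:
            parts += ["-P", job.project]
        if job.stdout_log:
            parts += ["-o", job.stdout_log]
        if job.stderr_log:
            parts += ["-e", job.stderr_log]
        return " ".join(parts) + f" {job.command}"
    raise SchedulerError(f"unknown scheduler backend: {backend!r}")


_REPLY_PATTERNS = {
    "slurm": re.compile(r"Submitted batch job (\d+)"),
    "gridengine": re.compile(r"Your job (\d+)"),
    "lsf": re.compile(r"Job <(\d+)>"),
}


def parse_submission_reply(backend: str, reply: str) -> str:
    pattern = _REPLY_PATTERNS.get(backend)
    if pattern is None:
        raise SchedulerError(f"unknown scheduler backend: {backend!r}")
    m = pattern.search(reply)
    if not m:
        raise SchedulerError(
            f"could not extract a job id from {backend} reply: {reply!r}"
        )
    return m.group(1)


CommandRunner = Callable[[str], "subprocess.CompletedProcess[str]"]


def _default_runner(cmd: str) -> "subprocess.CompletedProcess[str]":
    return subprocess.run(cmd, shell=True, capture_output=True, text=True)


def submit_plan(
    jobspecs: Sequence[JobSpec],
    backend: str,
    groups: Mapping[str, int] | None = None,
    dry_run: bool = False,
    runner: CommandRunner | None = None,
) -> dict[str, str] | list[str]:
    """Submit jobs in the given (topological) order.

    *jobspecs* reference upstream jobs by *name* in ``dependency``; each
    downstream submission is rewritten to embed the scheduler-assigned id
    of its upstream.  With ``dry_run`` the full ordered command list is
    returned with ``<name>`` placeholder ids and nothing is executed.
    A submission failure aborts the remaining jobs of the *same* input
    group (they could never satisfy their holds) but other groups proceed.
    """
    if backend not in _REPLY_PATTERNS:
        raise SchedulerError(f"unknown scheduler backend: {backend!r}")
    groups = groups or {}
    if dry_run:
        commands = []
        for job in jobspecs:
            shadow = JobSpec(**{**job.__dict__})
            if shadow.dependency:
                shadow.dependency = f"<{shadow.dependency}>"
            commands.append(make_submit_command(backend, shadow))
        return commands
    runner = runner or _default_runner
    ids: dict[str, str] = {}
    failed_groups: set[int] = set()
    errors: list[str] = []
    for job in jobspecs:
        group = groups.get(job.name, 0)
        if group in failed_groups:
            continue
        resolved = JobSpec(**{**job.__dict__})
        if resolved.dependency:
            if resolved.dependency not in ids:
                failed_groups.add(group)
                errors.append(f"{job.name}: upstream {resolved.dependency} was never submitted")
                continue
            resolved.dependency = ids[resolved.dependency]
        proc = runner(make_submit_command(backend, resolved))
        if proc.returncode != 0:
            failed_groups.add(group)
            errors.append(f"{job.name}: submission failed: {proc.stderr.strip()[:200]}")
            continue
        ids[job.name] = parse_submission_reply(backend, proc.stdout)
    if errors:
        queued = ", ".join(ids) or "(none)"
        raise SchedulerError(
            "submission aborted for some groups: "
            + "; ".join(errors)
            + f". Jobs already queued: {queued}"
        )
    return ids


# ---------------------------------------------------------------------------
# local mode


@dataclass
class LocalJobResult:
    name: str
    status: str  # ok | fail | skipped
    returncode: int | None = None
    started: float | None = None
    finished: float | None = None


@dataclass
class LocalJob:
    """What the local executor needs to run one job."""

    name: str
    group: int
    upstream: str | None
    argv: list[str] = field(default_factory=list)
    log_path: str = ""


def run_local(
    jobs: Sequence[LocalJob],
    max_parallel_groups: int = 1,
    job_runner: Callable[[LocalJob], int] | None = None,
) -> dict[str, LocalJobResult]:
    """Execute a plan serially within each group.

    Jobs must be given in topological (depth-first) order per group.  A
    nonzero exit skips the failing job's descendants; sibling branches and
    other groups are unaffected.  Groups run in a small thread pool
    (subprocesses do the work; threads only babysit them).
    """
    by_group: dict[int, list[LocalJob]] = {}
    for job in jobs:
        by_group.setdefault(job.group, []).append(job)
    results: dict[str, LocalJobResult] = {}

    def default_runner(job: LocalJob) -> int:
        log = open(job.log_path, "a") if job.log_path else subprocess.DEVNULL
        try:
            exe = Path(job.argv[0])
            if not exe.exists():
                if job.log_path:
                    log.write(f"###CF_ERR wrapper not found: {exe}\n")
                return 127
            proc = subprocess.run(job.argv, stdout=log, stderr=subprocess.STDOUT)
            return proc.returncode
        finally:
            if job.log_path:
                log.close()

    run_one = job_runner or default_runner

    def run_group(group_jobs: list[LocalJob]) -> None:
        dead: set[str] = set()  # jobs that failed or were skipped
        for job in group_jobs:
            if job.upstream is not None and job.upstream in dead:
                results[job.name] = LocalJobResult(job.name, "skipped")
                dead.add(job.name)
                continue
            started = time.monotonic()
            try:
                rc = run_one(job)
            except OSError:
                rc = 127
            finished = time.monotonic()
            if rc == 0:
                results[job.name] = LocalJobResult(job.name, "ok", rc, started, finished)
            else:
                results[job.name] = LocalJobResult(job.name, "fail", rc, started, finished)
                dead.add(job.name)

    with ThreadPoolExecutor(max_workers=max(1, max_parallel_groups)) as pool:
        futures = [pool.submit(run_group, g) for g in by_group.values()]
        for fut in futures:
            fut.result()
    return results


def run_local_detached(plan_file: str | Path, log_path: str | Path) -> int:
    """Re-launch a serialized local plan as a detached background process.

    Returns the worker's PID; output is captured to *log_path*.  The worker
    is ``python -m flowlite._localworker <plan.json>``.
    """
    with open(log_path, "a") as log:
        proc = subprocess.Popen(
            [sys.executable, "-m", "flowlite._localworker", str(plan_file)],
            stdout=log,
            stderr=subprocess.STDOUT,
            start_new_session=True,
        )
    return proc.pid
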