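"""Composition of a full launch: inputs -> groups -> plan -> submission.

The sequence mirrors what a user types: resolve inputs (including URLs),
apply configured lane-merge regexes, group paired files, create run files,
negotiate resources with each wrapper, and hand the plan to the chosen
backend (or the local executor, or just print it for a dry run).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
import os
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import helpers, runfile as rf
from .config import ConfigSet, GenomeRef, lookup_genome
from .module_api import (
    ModuleInvocation,
    ResourceRequest,
    build_invocation,
    query_requirements,
    wrapper_argv,
)
from .pipeline import JobPlan, Pipeline, PlannedJob, parse_pipeline, plan_jobs
from .scheduler import JobSpec, LocalJob, run_local, submit_plan
from .wrappers import module_registry

log = logging.getLogger(__name__)

DOWNLOAD_MODULE = "download"


class LaunchError(Exception):
    pass


@dataclass
class LaunchRequest:
    pipeline: Pipeline
    inputs: Sequence[str]
    config: ConfigSet
    genomes: Sequence[GenomeRef] = ()
    genome_id: str | None = None
    params: Sequence[str] = ()
    local: bool = False
    dry_run: bool = False
    email: str | None = None
    run_dir: str | os.PathLike = "."
    module_dirs: Sequence[str] = ()
    defer_local: bool = False  # plan + run files, but let the caller execute


@dataclass
class LaunchResult:
    run_id: str
    runfiles: list[Path] = field(default_factory=list)
    groups: list[helpers.FileGroup] = field(default_factory=list)
    plan: JobPlan | None = None
    dry_run_commands: list[str] = field(default_factory=list)
    scheduler_ids: dict[str, str] = field(default_factory=dict)
    local_results: dict[str, object] = field(default_factory=dict)
    local_jobs: list[LocalJob] = field(default_factory=list)
    summary: str = ""


def load_packaged_pipeline(name: str, extra_dirs: Sequence[str | os.PathLike] = ()) -> Pipeline:
    """Find ``<name>.config`` in user dirs (first) then the packaged dir."""
    candidates = [Path(d) / f"{name}.config" for d in extra_dirs]
    candidates.append(Path(__file__).parent / "pipelines" / f"{name}.config")
    for path in candidates:
        if path.exists():
            return parse_pipeline(path.read_text(), name=name)
    available = sorted(
        p.stem for p in (Path(__file__).parent / "pipelines").glob("*.config")
    )
    raise LaunchError(
        f"unknown pipeline {name!r}; packaged pipelines: {', '.join(available)}"
    )


def list_packaged_pipelines() -> list[str]:
    return sorted(p.stem for p in (Path(__file__).parent / "pipelines").glob("*.config"))


def single_module_pipeline(module: str) -> Pipeline:
    """Ad-hoc one-step pipeline so any module can be run directly."""
    return parse_pipeline(f"#{module}\n", name=module)


def _with_download_root(pipe: Pipeline) -> Pipeline:
    """Prepend a download step that all original roots wait on."""
    text = f"#{DOWNLOAD_MODULE}\n" + "\n".join(
        "\t" + line for line in _render_body(pipe).splitlines()
    )
    downloaded = parse_pipeline(text, name=pipe.name)
    downloaded.directives = dict(pipe.directives)
    return downloaded


def _render_body(pipe: Pipeline) -> str:
    from .pipeline import render_pipeline

    return "\n".join(
        line for line in render_pipeline(pipe).splitlines() if not line.startswith("@")
    )


def make_run_id(now: _dt.datetime | None = None) -> str:
    now = now or _dt.datetime.now(_dt.timezone.utc)
    return now.strftime("%Y%m%d-%H%M%S")


def plan_for_groups(
    pipeline: Pipeline,
    groups: Sequence[helpers.FileGroup],
    url_groups: set[int],
    run_id: str,
) -> JobPlan:
    """Per-group planning: groups whose inputs are URLs get a download root
    prepended; job names carry the real group index."""
    jobs: list[PlannedJob] = []
    edges: list[tuple[str, str]] = []
    with_dl = _with_download_root(pipeline)
    for g, _group in enumerate(groups):
        pipe_g = with_dl if g in url_groups else pipeline
        sub = plan_jobs(pipe_g, 1, run_id=run_id)
        # deterministic names carrying the real group index, with collision
        # ordinals where a module recurs in the tree
        used: dict[str, int] = {}
        rename: dict[str, str] = {}
        for j in sub.jobs:
            base = f"cf_{pipeline.name}_{run_id}_{j.module_name}_{g}"
            n = used.get(base, 0)
            rename[j.name] = base if n == 0 else f"{base}_{n}"
            used[base] = n + 1
        for j in sub.jobs:
            jobs.append(
                dataclasses.replace(
                    j,
                    name=rename[j.name],
                    group=g,
                    upstream=rename[j.upstream] if j.upstream else None,
                )
            )
        edges += [(rename[a], rename[b]) for a, b in sub.edges]
    return JobPlan(jobs=jobs, edges=edges)


def prepare_inputs(
    raw_inputs: Sequence[str], config: ConfigSet, run_dir: str | os.PathLike, dry_run: bool
) -> tuple[list[helpers.FileGroup], set[int]]:
    """Resolve URLs, execute configured lane merges, group paired files.

    Returns the groups plus the set of group indices whose members are URLs
    (those get a download step prepended to their plan).
    """
    local, downloads = helpers.resolve_inputs(raw_inputs)
    merge_patterns = config.get_all("merge_regex")
    if merge_patterns and local:
        plan = helpers.apply_merge_regex(local, merge_patterns)
        if plan:
            merged_sources = {s for srcs in plan.values() for s in srcs}
            if dry_run:
                merged = list(plan.keys())
            else:
                merged = helpers.execute_merge(plan, out_dir=run_dir)
            local = [f for f in local if f not in merged_sources] + merged
    names = local + [d.filename for d in downloads]
    groups = helpers.group_paired_files(names)
    url_of = {d.filename: d.url for d in downloads}
    url_groups: set[int] = set()
    for idx, group in enumerate(groups):
        if any(m in url_of for m in group.members):
            group.members = [url_of.get(m, m) for m in group.members]
            url_groups.add(idx)
    return groups, url_groups


def launch(request: LaunchRequest) -> LaunchResult:
    """Run the full launch sequence; see module docstring.

    With ``dry_run`` nothing is written anywhere: run files are skipped and
    the ordered submission command list is returned instead.  A failure
    while processing one group leaves earlier groups' submissions standing
    (documented behaviour — scheduler holds make partial runs safe).
    """
    cfg = request.config
    pipeline = request.pipeline
    run_id = make_run_id()
    registry = module_registry(request.module_dirs)

    groups, url_groups = prepare_inputs(
        request.inputs, cfg, request.run_dir, request.dry_run
    )
    plan = plan_for_groups(pipeline, groups, url_groups, run_id)

    # fail before submission if a module or reference cannot be resolved
    needed_modules = sorted({j.module_name for j in plan.jobs})
    for mod in needed_modules:
        if mod not in registry:
            raise LaunchError(f"module {mod!r} not found in any modules directory")

    grants: dict[str, ResourceRequest] = {}
    genome_args: dict[str, list[str]] = {}
    for mod in needed_modules:
        n_files = max(len(g.members) for g in groups)
        grants[mod] = query_requirements(
            registry[mod], n_files, request.params, cfg, genome_id=request.genome_id
        )
        refs = []
        for ref_type in grants[mod].required_ref_types:
            if request.genome_id is None:
                raise LaunchError(
                    f"module {mod!r} needs a {ref_type!r} reference; pass --genome"
                )
            path = lookup_genome(request.genomes, request.genome_id, ref_type)
            refs.append(f"{ref_type}={path}")
        genome_args[mod] = refs

    # run files (skipped entirely on dry runs: zero side effects)
    if request.dry_run:
        runfiles = [
            Path(request.run_dir) / f"{pipeline.name}_{run_id}_{g}.run"
            for g in range(len(groups))
        ]
    else:
        runfiles = rf.create_runfiles(
            request.run_dir,
            pipeline,
            plan,
            {k: cfg.get(k) or "" for k in ("cluster_environment", "max_cores", "max_mem")},
            [g.members for g in groups],
            run_id,
            genome_id=request.genome_id,
        )

    all_params = list(request.params)
    jobspecs: list[JobSpec] = []
    local_jobs: list[LocalJob] = []
    groups_of: dict[str, int] = {}
    for job in plan.jobs:
        grant = grants[job.module_name]
        inv = ModuleInvocation(
            wrapper=str(registry[job.module_name]),
            runfile=str(runfiles[job.group]),
            job_id=job.name,
            prev_job_id=job.upstream or rf.START_SENTINEL,
            cores=grant.cores,
            memory=grant.memory,
            params=tuple(job.params) + tuple(all_params),
            genome_paths=tuple(genome_args[job.module_name]),
        )
        command = build_invocation(inv)
        log_base = Path(request.run_dir) / f"{job.name}"
        jobspecs.append(
            JobSpec(
                name=job.name,
                command=command,
                dependency=job.upstream,
                cores=grant.cores,
                memory=grant.memory,
                time=grant.time,
                queue=cfg.get("queue"),
                project=cfg.get("project"),
                stdout_log=f"{log_base}.log",
                stderr_log=f"{log_base}.log",
            )
        )
        groups_of[job.name] = job.group
        local_jobs.append(
            LocalJob(
                name=job.name,
                group=job.group,
                upstream=job.upstream,
                argv=wrapper_argv(shlex.split(command)[0], shlex.split(command)[1:]),
                log_path=str(Path(request.run_dir) / f"{pipeline.name}_{run_id}_{job.group}.log"),
            )
        )

    result = LaunchResult(
        run_id=run_id, runfiles=list(runfiles), groups=groups, plan=plan,
        local_jobs=local_jobs,
    )
    per_group = len(plan.jobs) // max(1, len(groups))
    result.summary = (
        f"Pipeline {pipeline.name}: {len(groups)} input group(s), "
        f"{len(plan.jobs)} job(s) ({per_group} per group)"
    )

    backend = "local" if request.local else cfg.get("cluster_environment", "local")
    if request.dry_run:
        if backend in {"local", ""}:
            result.dry_run_commands = [
                shlex.join(j.argv) for j in local_jobs
            ]
        else:
            result.dry_run_commands = submit_plan(jobspecs, backend, dry_run=True)
        return result

    if backend in {"local", ""}:
        if request.defer_local:
            return result
        result.local_results = run_local(
            local_jobs, max_parallel_groups=int(cfg.get("max_parallel_groups", "2") or 2)
        )
        group_of = {j.name: j.group for j in plan.jobs}
        write_reports(
            result.runfiles,
            result.local_results,
            group_of,
            email=request.email or cfg.get("email", "") or "",
        )
    else:
        result.scheduler_ids = submit_plan(jobspecs, backend, groups=groups_of)
    return result


def write_reports(
    runfiles: Sequence[Path],
    local_results: dict[str, object],
    group_of: dict[str, int],
    email: str = "",
) -> None:
    """Post-run reporting for local mode: parse each group's log, render
    text/HTML, write the e-mail files and the versions sidecar."""
    from . import reporting

    for g, run_path in enumerate(runfiles):
        run_path = Path(run_path)
        log_path = run_path.with_suffix(".log")
        text = log_path.read_text() if log_path.exists() else ""
        events = reporting.parse_run_log(text)
        data = rf.parse_runfile(run_path)
        report = reporting.build_report(events, data)
        # jobs skipped by the executor never reach the log; surface them
        for name, res in local_results.items():
            if getattr(res, "status", "") == "skipped" and group_of.get(name) == g:
                report.errors.append(f"job {name} skipped (upstream failure)")
                report.outcome = "errors"
        txt = reporting.render_text(report)
        html_doc = reporting.render_html(report)
        run_path.with_name(run_path.stem + "_report.txt").write_text(txt)
        run_path.with_name(run_path.stem + "_report.html").write_text(html_doc)
        reporting.write_versions_file(report, run_path.with_name(run_path.stem + "_versions.txt"))
        sender = reporting.FileSender(run_path.parent, recipient=email)
        sender.send(report, txt, html_doc)
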