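"""Submission command dialects, dependency chaining, local serial execution."""

from __future__ import annotations

import random
import re
from types import SimpleNamespace

import pytest

from flowlite.pipeline import parse_pipeline, plan_jobs
from flowlite.scheduler import (
    JobSpec,
    LocalJob,
    SchedulerError,
    make_submit_command,
    parse_submission_reply,
    run_local,
    submit_plan,
)
from .conftest import random_pipeline


def spec(name="cf_x_1_mod_0", dep=None):
    return JobSpec(name=name, command="wrapper --run_fn x.run", dependency=dep,
                   cores=4, memory=8 * 2**30, time=120)


class TestSubmitCommands:
    def test_slurm_dialect(self):
        cmd = make_submit_command("slurm", spec(dep="4242"))
        assert cmd.startswith("sbatch ")
        assert "--dependency=afterok:4242" in cmd
        assert "--cpus-per-task=4" in cmd
        assert "--mem=8192M" in cmd  # slurm memory is MB

    def test_gridengine_dialect(self):
        cmd = make_submit_command("gridengine", spec(dep="17"))
        assert cmd.startswith("qsub ")
        assert "-hold_jid 17" in cmd
        assert "-pe smp 4" in cmd
        assert "h_vmem=2G" in cmd  # per-core memory: 8G / 4 cores

    def test_lsf_dialect(self):
        cmd = make_submit_command("lsf", spec(dep="17"))
        assert cmd.startswith("bsub ")
        assert '-w "done(17)"' in cmd
        assert "-n 4" in cmd

    def test_no_dependency_emits_no_hold(self):
        for backend, token in [("slurm", "--dependency"), ("gridengine", "-hold_jid"),
                               ("lsf", "-w ")]:
            assert token not in make_submit_command(backend, spec())

    def test_unknown_backend_fatal(self):
        with pytest.raises(SchedulerError):
            make_submit_command("pbs", spec())


class TestReplies:
    @pytest.mark.parametrize(
        "backend,reply,expected",
        [
            ("slurm", "Submitted batch job 4242", "4242"),
            ("gridengine", 'Your job 17 ("cf_x") has been submitted', "17"),
            ("lsf", "Job <123> is submitted to default queue <normal>.", "123"),
        ],
    )
    def test_id_extraction(self, backend, reply, expected):
        assert parse_submission_reply(backend, reply) == expected

    def test_unmatched_reply_fatal_with_raw_text(self):
        with pytest.raises(SchedulerError, match="qsub: command not found"):
            parse_submission_reply("slurm", "qsub: command not found")


def scripted_runner(replies=None, fail_names=()):
    """Fake scheduler: returns sequential ids, fails for chosen job names."""
    counter = [100]

    def run(cmd):
        name = re.search(r"--job-name=(\S+)|-N (\S+)|-J (\S+)", cmd)
        jobname = next(g for g in name.groups() if g) if name else "?"
        if any(f in jobname for f in fail_names):
            return SimpleNamespace(returncode=1, stdout="", stderr="quota exceeded")
        counter[0] += 1
        return SimpleNamespace(returncode=0, stdout=f"Submitted batch job {counter[0]}", stderr="")

    return run


class TestSubmitPlan:
    def jobs(self, pipe_text="#a\n\t#b\n", n_groups=1):
        plan = plan_jobs(parse_pipeline(pipe_text), n_groups)
        specs = [
            JobSpec(name=j.name, command=f"run {j.name}", dependency=j.upstream)
            for j in plan.jobs
        ]
        groups = {j.name: j.group for j in plan.jobs}
        return specs, groups

    def test_dry_run_two_step_linear(self):
        specs, _ = self.jobs()
        cmds = submit_plan(specs, "slurm", dry_run=True)
        assert len(cmds) == 2
        assert f"afterok:<{specs[0].name}>" in cmds[1]

    def test_dry_run_byte_identical(self):
        specs, _ = self.jobs("#a\n\t#b\n\t#c\n", 2)
        assert submit_plan(specs, "slurm", dry_run=True) == submit_plan(
            specs, "slurm", dry_run=True
        )

    def test_empty_plan(self):
        assert submit_plan([], "slurm", dry_run=True) == []
        assert submit_plan([], "slurm", runner=scripted_runner()) == {}

    def test_downstream_embeds_scheduler_assigned_id(self):
        specs, groups = self.jobs()
        seen = []

        def runner(cmd):
            seen.append(cmd)
            return SimpleNamespace(returncode=0, stdout=f"Submitted batch job {4000 + len(seen)}", stderr="")

        ids = submit_plan(specs, "slurm", groups=groups, runner=runner)
        assert ids[specs[0].name] == "4001"
        assert "afterok:4001" in seen[1]

    def test_failure_in_one_group_leaves_others_queued(self):
        specs, groups = self.jobs("#a\n\t#b\n", n_groups=3)
        fail_name = next(n for n in groups if groups[n] == 1 and "_a_" in n)
        runner = scripted_runner(fail_names=[fail_name])
        with pytest.raises(SchedulerError) as exc:
            submit_plan(specs, "slurm", groups=groups, runner=runner)
        msg = str(exc.value)
        queued = [n for n in groups if n in msg.split("already queued:")[1]]
        assert {groups[n] for n in queued} == {0, 2}
        assert all(groups[n] != 1 for n in queued)

    def test_dependency_placeholders_precede_dependents_randomized(self):
        rng = random.Random(17)
        for _ in range(30):
            pipe = random_pipeline(rng)
            plan = plan_jobs(pipe, rng.randint(1, 3))
            specs = [JobSpec(name=j.name, command="c", dependency=j.upstream) for j in plan.jobs]
            for backend in ("slurm", "gridengine", "lsf"):
                cmds = submit_plan(specs, backend, dry_run=True)
                for i, cmd in enumerate(cmds):
                    for ref in re.findall(r"<(cf_[^>]+)>", cmd):
                        earlier = [s.name for s in specs[:i]]
                        assert ref in earlier


class TestRunLocal:
    def run(self, pipe_text, rc_map, n_groups=1, trace=None):
        plan = plan_jobs(parse_pipeline(pipe_text), n_groups)
        jobs = [LocalJob(name=j.name, group=j.group, upstream=j.upstream) for j in plan.jobs]

        def runner(job):
            if trace is not None:
                trace.append(job.name)
            key = next(k for k in rc_map if f"_{k}_" in job.name)
            return rc_map[key]

        return plan, run_local(jobs, job_runner=runner)

    def test_failure_skips_descendants_only(self):
        plan, results = self.run("#a\n\t#b\n\t\t#c\n", {"a": 0, "b": 1, "c": 0})
        by_mod = {j.module_name: results[j.name].status for j in plan.jobs}
        assert by_mod == {"a": "ok", "b": "fail", "c": "skipped"}

    def test_parallel_branch_survives_sibling_failure(self):
        plan, results = self.run("#a\n\t#b\n\t#c\n\t\t#d\n", {"a": 0, "b": 1, "c": 0, "d": 0})
        by_mod = {j.module_name: results[j.name].status for j in plan.jobs}
        assert by_mod == {"a": "ok", "b": "fail", "c": "ok", "d": "ok"}

    def test_empty_plan(self):
        assert run_local([]) == {}

    def test_missing_wrapper_records_failure(self, tmp_path):
        job = LocalJob(name="j", group=0, upstream=None,
                       argv=[str(tmp_path / "nope")], log_path=str(tmp_path / "j.log"))
        results = run_local([job])
        assert results["j"].status == "fail"

    def test_start_times_nondecreasing_along_paths(self):
        rng = random.Random(23)
        for _ in range(10):
            pipe = random_pipeline(rng)
            plan = plan_jobs(pipe, 2)
            jobs = [LocalJob(name=j.name, group=j.group, upstream=j.upstream) for j in plan.jobs]
            results = run_local(jobs, max_parallel_groups=2, job_runner=lambda j: 0)
            upstream = {j.name: j.upstream for j in plan.jobs}
            for name, up in upstream.items():
                if up is not None:
                    assert results[up].started <= results[name].started
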