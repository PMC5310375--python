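"""Run-file creation, append-only body, status derivation, crash safety."""

from __future__ import annotations

import os
import random
import threading

import pytest

from flowlite.pipeline import parse_pipeline, plan_jobs
from flowlite.runfile import (
    MARK_DONE,
    MARK_FAIL,
    MARK_START,
    START_SENTINEL,
    RunFileError,
    append_marker,
    append_outputs,
    create_runfiles,
    derive_status,
    inputs_for,
    parse_runfile,
    status,
)

PIPE = "#fastqc\n#trim_galore\n\t#bowtie2\n"


def make_run(tmp_path, groups=(("a_R1.fq.gz", "a_R2.fq.gz"), ("b.fq.gz",)), pipe_text=PIPE):
    pipe = parse_pipeline(pipe_text, name="p")
    plan = plan_jobs(pipe, len(groups), run_id="r1")
    paths = create_runfiles(tmp_path, pipe, plan, {"max_cores": "8"}, groups, "r1")
    return pipe, plan, paths


class TestCreate:
    def test_one_file_per_group_with_own_inputs(self, tmp_path):
        _, _, paths = make_run(tmp_path)
        assert len(paths) == 2
        data0 = parse_runfile(paths[0])
        assert inputs_for(data0, START_SENTINEL) == ["a_R1.fq.gz", "a_R2.fq.gz"]
        data1 = parse_runfile(paths[1])
        assert inputs_for(data1, START_SENTINEL) == ["b.fq.gz"]

    def test_paired_group_gets_two_sentinel_lines(self, tmp_path):
        _, _, paths = make_run(tmp_path)
        lines = [l for l in paths[0].read_text().splitlines() if l.startswith(START_SENTINEL)]
        assert len(lines) == 2

    def test_header_records_planned_jobs(self, tmp_path):
        _, plan, paths = make_run(tmp_path)
        header = parse_runfile(paths[0]).header
        assert len(header.jobs) == 3
        assert {j[1] for j in header.jobs} == {"fastqc", "trim_galore", "bowtie2"}

    def test_collision_increments_suffix_never_overwrites(self, tmp_path):
        _, _, first = make_run(tmp_path, groups=(("x.fq",),))
        _, _, second = make_run(tmp_path, groups=(("y.fq",),))
        assert first[0] != second[0]
        assert first[0].exists() and second[0].exists()
        assert inputs_for(parse_runfile(first[0]), START_SENTINEL) == ["x.fq"]

    def test_unwritable_dir_fatal_before_submission(self, tmp_path, monkeypatch):
        # file modes don't bind the root user, so stub the writability probe
        monkeypatch.setattr(os, "access", lambda *a, **k: False)
        with pytest.raises(RunFileError, match="not writable"):
            make_run(tmp_path)


class TestAppend:
    def test_append_preserves_header(self, tmp_path):
        _, plan, paths = make_run(tmp_path)
        before_header = paths[0].read_text().split("*/")[0]
        append_outputs(paths[0], plan.jobs[0].name, ["out1.fq", "out2.fq"])
        text = paths[0].read_text()
        assert text.split("*/")[0] == before_header
        assert text.count("out1.fq") == 1

    def test_unknown_job_id_warns_but_records(self, tmp_path, caplog):
        _, plan, paths = make_run(tmp_path)
        known = [j.name for j in plan.jobs]
        with caplog.at_level("WARNING"):
            append_outputs(paths[0], "mystery_job", ["x.fq"], known_jobs=known)
        assert any("unplanned" in r.message for r in caplog.records)
        assert "mystery_job\tx.fq" in paths[0].read_text()

    def test_concurrent_appends_never_interleave(self, tmp_path):
        _, plan, paths = make_run(tmp_path)
        n_threads, n_lines = 8, 50

        def writer(t):
            for i in range(n_lines):
                append_outputs(paths[0], f"job_t{t}", [f"file_t{t}_{i}.fq"])

        threads = [threading.Thread(target=writer, args=(t,)) for t in range(n_threads)]
        for th in threads:
            th.start()
        for th in threads:
            th.join()
        body = [l for l in paths[0].read_text().splitlines() if l.startswith("job_t")]
        assert len(body) == n_threads * n_lines
        assert all(len(l.split("\t")) == 2 and l.split("\t")[1].endswith(".fq") for l in body)


class TestInputsFor:
    def test_first_step_sees_original_inputs(self, tmp_path):
        _, _, paths = make_run(tmp_path)
        assert inputs_for(paths[0], START_SENTINEL) == ["a_R1.fq.gz", "a_R2.fq.gz"]

    def test_pass_through_resolves_transitively(self, tmp_path):
        # fastqc-style QC step records no outputs: the step after it must see
        # the QC step's own inputs
        _, plan, paths = make_run(tmp_path, groups=(("x.fq",),), pipe_text="#fastqc\n\t#bowtie2\n")
        qc = plan.jobs[0].name
        append_marker(paths[0], qc, MARK_DONE)
        assert inputs_for(paths[0], qc) == ["x.fq"]

    def test_unknown_id_yields_empty(self, tmp_path):
        _, _, paths = make_run(tmp_path)
        assert inputs_for(paths[0], "no_such_job") == []


class TestStatus:
    def test_fresh_run_all_queued(self, tmp_path):
        _, _, paths = make_run(tmp_path)
        st = derive_status(parse_runfile(paths[0]))
        assert [s.state for s in st.steps] == ["queued"] * 3
        assert st.remaining == 3
        assert st.duration_seconds >= 0

    def test_all_done_zero_remaining(self, tmp_path):
        _, plan, paths = make_run(tmp_path, groups=(("x.fq",),))
        for j in plan.jobs:
            append_marker(paths[0], j.name, MARK_START, "2026-01-01T00:00:00+00:00")
            append_marker(paths[0], j.name, MARK_DONE, "2026-01-01T01:00:00+00:00")
        st = derive_status(parse_runfile(paths[0]))
        assert {s.state for s in st.steps} == {"done"}
        assert st.remaining == 0

    def test_failed_step_skips_descendants(self, tmp_path):
        # linear 3-step run: step 2 fails, step 3 is derived as skipped
        _, plan, paths = make_run(
            tmp_path, groups=(("x.fq",),), pipe_text="#fastqc\n\t#trim_galore\n\t\t#bowtie2\n"
        )
        j1, j2, j3 = [j.name for j in plan.jobs]
        append_marker(paths[0], j1, MARK_START)
        append_marker(paths[0], j1, MARK_DONE)
        append_marker(paths[0], j2, MARK_START)
        append_marker(paths[0], j2, MARK_FAIL)
        by_job = {s.job_id: s.state for s in derive_status(parse_runfile(paths[0])).steps}
        assert by_job == {j1: "done", j2: "failed", j3: "skipped"}

    def test_running_state_from_start_without_end(self, tmp_path):
        _, plan, paths = make_run(tmp_path, groups=(("x.fq",),))
        append_marker(paths[0], plan.jobs[0].name, MARK_START)
        states = {s.job_id: s.state for s in derive_status(parse_runfile(paths[0])).steps}
        assert states[plan.jobs[0].name] == "running"

    def test_duration_from_header_to_last_event(self, tmp_path):
        _, plan, paths = make_run(tmp_path, groups=(("x.fq",),))
        created = parse_runfile(paths[0]).header.created
        import datetime as dt

        later = (dt.datetime.fromisoformat(created) + dt.timedelta(hours=2)).isoformat()
        append_marker(paths[0], plan.jobs[0].name, MARK_START, later)
        st = derive_status(parse_runfile(paths[0]))
        assert st.duration_seconds == pytest.approx(7200)
        assert st.duration_human == "2h 0m"

    def test_status_scan_skips_non_dirs_and_finds_runs(self, tmp_path):
        make_run(tmp_path)
        out = status([tmp_path, tmp_path / "missing"])
        assert len(out) == 2

    def test_truncation_fuzz_never_raises(self, tmp_path):
        """Crash safety: every byte-prefix of a valid run file is parseable
        and yields a derivable status."""
        _, plan, paths = make_run(tmp_path)
        for j in plan.jobs:
            append_marker(paths[0], j.name, MARK_START)
            append_outputs(paths[0], j.name, ["out.fq"])
            append_marker(paths[0], j.name, MARK_DONE)
        blob = paths[0].read_bytes()
        rng = random.Random(1)
        cuts = sorted(rng.sample(range(len(blob)), min(200, len(blob))))
        trunc = tmp_path / "trunc.run"
        for cut in cuts:
            trunc.write_bytes(blob[:cut])
            st = derive_status(parse_runfile(trunc))  # must not raise
            assert len(st.steps) <= len(plan.jobs)

    def test_statelessness_same_contents_same_status(self, tmp_path):
        _, plan, paths = make_run(tmp_path, groups=(("x.fq",),))
        for j in plan.jobs:
            append_marker(paths[0], j.name, MARK_START, "2026-01-01T00:00:00+00:00")
            append_marker(paths[0], j.name, MARK_DONE, "2026-01-01T00:05:00+00:00")
        a = derive_status(parse_runfile(paths[0]))
        b = derive_status(parse_runfile(paths[0]))
        assert a == b

    def test_body_line_conservation(self, tmp_path):
        _, plan, paths = make_run(tmp_path, groups=(("x.fq", "y.fq"),))
        outputs = {plan.jobs[0].name: ["a.fq"], plan.jobs[1].name: ["b.fq", "c.fq"]}
        for job, outs in outputs.items():
            append_outputs(paths[0], job, outs)
        data = parse_runfile(paths[0])
        plain = [f for f in data.body if f[1] not in {MARK_START, MARK_DONE, MARK_FAIL}]
        assert len(plain) == 2 + sum(len(v) for v in outputs.values())
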