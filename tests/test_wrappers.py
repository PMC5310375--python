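"""Packaged wrapper roster, command generation, stubs, synthetic FastQ."""

from __future__ import annotations

import gzip
import os
import subprocess

import pytest

from flowlite.helpers import FileGroup
from flowlite.module_api import ResourceRequest, negotiate, query_requirements
from flowlite.wrappers import (
    PACKAGED,
    WrapperError,
    generate_command,
    list_packaged_modules,
    module_registry,
    outputs_for,
    packaged_modules_dir,
    sample_stem,
)
from flowlite.wrappers.runner import _requirements_text
from flowlite.wrappers.specs import BY_NAME
from flowlite.wrappers.stubs import make_stub_toolbox, make_synthetic_fastq


class TestRegistry:
    def test_packaged_module_count(self):
        assert len(list_packaged_modules()) == 40

    def test_specs_and_executables_agree(self):
        assert set(list_packaged_modules()) == set(BY_NAME)

    def test_user_dir_adds_module(self, tmp_path):
        (tmp_path / "mytool.py").write_text("# user module\n")
        reg = module_registry([tmp_path])
        assert "mytool" in reg
        assert len(reg) == len(module_registry()) + 1

    def test_user_module_shadows_packaged_count_unchanged(self, tmp_path):
        (tmp_path / "fastqc.py").write_text("# shadowing module\n")
        reg = module_registry([tmp_path])
        assert reg["fastqc"] == tmp_path / "fastqc.py"
        assert len(reg) == len(module_registry())


class TestRequirementsProtocol:
    def test_every_packaged_wrapper_negotiates(self, base_config):
        """Each wrapper's requirements text parses and clamps cleanly."""
        for spec in PACKAGED:
            raw = {}
            for line in _requirements_text(spec.name).splitlines():
                k, _, v = line.partition(":")
                raw[k.strip()] = v.strip()
            grant = negotiate(raw, n_files=2, config=base_config, module=spec.name)
            assert 1 <= grant.cores <= base_config.max_cores
            assert grant.memory <= base_config.max_mem_bytes
            assert grant.time >= 1

    def test_subprocess_protocol_round_trip(self, base_config):
        grant = query_requirements(
            packaged_modules_dir() / "bowtie2.py", n_files=3, params=[], config=base_config
        )
        assert grant.required_ref_types == ["bowtie2"]
        assert grant.cores == 8


GRANT = ResourceRequest(cores=4, memory=8 * 2**30)


class TestGenerateCommand:
    def test_trimmer_paired_with_custom_param(self):
        group = FileGroup("a", ["a_R1.fq.gz", "a_R2.fq.gz"], "paired")
        (cmd,) = generate_command("trim_galore", group, params=["clip_r1=3"], granted=GRANT)
        assert cmd == "trim_galore --cores 4 --paired a_R1.fq.gz a_R2.fq.gz --clip_r1 3"

    def test_aligner_thread_flag_carries_grant(self):
        group = FileGroup("a", ["a.fq.gz"], "single")
        (cmd,) = generate_command(
            "bowtie2", group, genome_paths={"bowtie2": "/refs/idx"}, granted=GRANT
        )
        assert cmd == "bowtie2 -p 4 -x /refs/idx -U a.fq.gz"

    def test_missing_required_genome_fatal_naming_both(self):
        group = FileGroup("a", ["a.fq.gz"], "single")
        with pytest.raises(WrapperError, match="bowtie2.*bowtie2"):
            generate_command("bowtie2", group, granted=GRANT)

    def test_paired_group_on_single_only_template_fatal(self):
        group = FileGroup("a", ["a_R1.fq.gz", "a_R2.fq.gz"], "paired")
        with pytest.raises(WrapperError, match="paired-end"):
            generate_command("bwa_aln", group, genome_paths={"bwa": "/r"}, granted=GRANT)

    def test_generation_deterministic_golden(self):
        group = FileGroup("s", ["s_R1.fq.gz", "s_R2.fq.gz"], "paired")
        golden = generate_command("star", group, genome_paths={"star": "/refs/star"}, granted=GRANT)
        assert golden == [
            "STAR --runThreadN 4 --genomeDir /refs/star --readFilesIn s_R1.fq.gz s_R2.fq.gz"
        ]
        for _ in range(3):
            assert generate_command(
                "star", group, genome_paths={"star": "/refs/star"}, granted=GRANT
            ) == golden

    def test_every_wrapper_generates_for_its_layouts(self):
        """Command construction is total over the packaged roster."""
        genome = {t: f"/refs/{t}" for s in PACKAGED for t in s.required_ref_types}
        for spec in PACKAGED:
            if spec.single:
                cmds = generate_command(
                    spec, ["x.fastq.gz"], genome_paths=genome, granted=GRANT
                )
                assert cmds and all(spec.tool in c.split()[0] for c in cmds)
            if spec.paired:
                group = FileGroup("x", ["x_R1.fastq.gz", "x_R2.fastq.gz"], "paired")
                cmds = generate_command(spec, group, genome_paths=genome, granted=GRANT)
                assert cmds

    def test_per_input_outputs_follow_inputs(self):
        spec = BY_NAME["trim_galore"]
        outs = outputs_for(spec, ["a_R1.fq.gz", "a_R2.fq.gz"])
        assert outs == ["a_R1_trimmed.fq.gz", "a_R2_trimmed.fq.gz"]

    def test_sample_stem_strips_tokens_and_extensions(self):
        assert sample_stem("proj_R1.fastq.gz") == "proj"
        assert sample_stem("a_R1_trimmed.fq.gz") == "a"
        assert sample_stem("plain.bam") == "plain"


class TestStubToolbox:
    def test_stub_creates_declared_outputs(self, tmp_path, stub_path):
        env = dict(os.environ)
        env["CF_STUB_OUTPUTS"] = os.pathsep.join(["o1.txt", "o2.fq.gz"])
        proc = subprocess.run(
            [str(stub_path / "fastqc"), "in.fq"], cwd=tmp_path, env=env,
            capture_output=True, text=True,
        )
        assert proc.returncode == 0
        assert "argv: in.fq" in proc.stdout
        assert (tmp_path / "o1.txt").exists()
        with gzip.open(tmp_path / "o2.fq.gz", "rt") as fh:
            assert fh.read().startswith("@stub")

    def test_stub_version_probe(self, stub_path):
        proc = subprocess.run(
            [str(stub_path / "bowtie2"), "--version"], capture_output=True, text=True
        )
        assert proc.stdout.strip() == "bowtie2 0.0.1-stub"

    def test_stub_fail_flag(self, stub_path):
        proc = subprocess.run([str(stub_path / "bowtie2"), "--fail"], capture_output=True)
        assert proc.returncode == 1

    def test_one_stub_per_distinct_tool(self, tmp_path):
        stubs = make_stub_toolbox(tmp_path / "t")
        assert set(stubs) == {s.tool for s in PACKAGED}


class TestSyntheticFastq:
    def test_record_count_and_quality_band(self, tmp_path):
        (path,) = make_synthetic_fastq(tmp_path, n_reads=10, read_len=50, seed=1)
        with gzip.open(path, "rt") as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 40
        quals = "".join(lines[3::4])
        assert min(ord(c) for c in quals) >= 33
        assert min(ord(c) for c in quals) < 59

    def test_paired_mode_identical_ids(self, tmp_path):
        r1, r2 = make_synthetic_fastq(tmp_path, paired=True, n_reads=5, seed=2)
        with gzip.open(r1, "rt") as a, gzip.open(r2, "rt") as b:
            ids_a = a.read().splitlines()[0::4]
            ids_b = b.read().splitlines()[0::4]
        assert ids_a == ids_b

    def test_same_seed_byte_identical(self, tmp_path):
        (a,) = make_synthetic_fastq(tmp_path / "x", n_reads=8, seed=7)
        (b,) = make_synthetic_fastq(tmp_path / "y", n_reads=8, seed=7)
        assert a.read_bytes() == b.read_bytes()
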