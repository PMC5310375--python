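"""Paired-end grouping, encoding detection, merge regexes, URL inputs."""

from __future__ import annotations

import gzip
import random

import pytest

from flowlite.helpers import (
    PAIR_TOKENS,
    InputError,
    apply_merge_regex,
    detect_fastq_encoding,
    execute_merge,
    group_paired_files,
    resolve_inputs,
)
from flowlite.wrappers.stubs import make_synthetic_fastq


class TestPairing:
    def test_r1_r2_pair(self):
        groups = group_paired_files(["a_R1.fastq.gz", "a_R2.fastq.gz"])
        assert len(groups) == 1
        g = groups[0]
        assert g.group_id == "a" and g.is_paired
        assert g.members == ["a_R1.fastq.gz", "a_R2.fastq.gz"]  # read1 first

    def test_numeric_tokens_and_singles(self):
        groups = group_paired_files(["a_1.fq", "a_2.fq", "b.fq"])
        layouts = {g.group_id: g.layout for g in groups}
        assert layouts == {"a": "paired", "b": "single"}

    def test_orphan_r2_demoted_to_single_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            groups = group_paired_files(["x_R2.fastq.gz"])
        assert groups[0].layout == "single"
        assert any("no read-1" in r.message for r in caplog.records)

    def test_output_sorted_by_group_id(self):
        groups = group_paired_files(["z.fq", "a_R1.fq", "a_R2.fq", "m.fq"])
        assert [g.group_id for g in groups] == ["a", "m", "z"]

    def test_partition_conserves_input_multiset(self):
        rng = random.Random(4)
        names = self.random_names(rng, 60)
        groups = group_paired_files(names)
        flat = [m for g in groups for m in g.members]
        assert sorted(flat) == sorted(names)

    @staticmethod
    def random_names(rng, n):
        """Unique sample stems; ~half planted as pairs, rest singles."""
        names, used = [], set()
        while len(names) < n:
            stem = "s" + "".join(rng.choice("abcdefgh") for _ in range(6))
            if stem in used:
                continue
            used.add(stem)
            if rng.random() < 0.5 and len(names) + 2 <= n:
                t1, t2 = rng.choice(PAIR_TOKENS)
                names += [f"{stem}{t1}.fastq.gz", f"{stem}{t2}.fastq.gz"]
            else:
                names.append(f"{stem}.fastq.gz")
        rng.shuffle(names)
        return names

    @staticmethod
    def brute_force_pairs(names):
        """O(n^2) oracle: all-pairs read-token comparison."""
        import os
        import re

        def stem(n):
            return re.sub(r"(\.(fastq|fq|txt|sra))?(\.gz)?$", "", os.path.basename(n))

        pairs = set()
        taken = set()
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if a in taken or b in taken:
                    continue
                for t1, t2 in PAIR_TOKENS:
                    sa, sb = stem(a), stem(b)
                    if sa.endswith(t1) and sb.endswith(t2) and sa[: -len(t1)] == sb[: -len(t2)]:
                        pairs.add((a, b))
                        taken |= {a, b}
                    elif sa.endswith(t2) and sb.endswith(t1) and sa[: -len(t2)] == sb[: -len(t1)]:
                        pairs.add((b, a))
                        taken |= {a, b}
        singles = {n for n in names if n not in taken}
        return pairs, singles

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = random.Random(42)
        for trial in range(50):
            names = self.random_names(rng, rng.randint(2, 50))
            groups = group_paired_files(names)
            got_pairs = {tuple(g.members) for g in groups if g.is_paired}
            got_singles = {g.members[0] for g in groups if not g.is_paired}
            want_pairs, want_singles = self.brute_force_pairs(names)
            assert got_pairs == want_pairs, f"trial {trial}"
            assert got_singles == want_singles, f"trial {trial}"


class TestEncodingDetection:
    def test_synthetic_phred33_and_phred64_recovered(self, tmp_path):
        for seed in range(5):
            for enc in ("phred33", "phred64"):
                (path,) = make_synthetic_fastq(
                    tmp_path, sample=f"{enc}{seed}", n_reads=50, encoding=enc, seed=seed
                )
                assert detect_fastq_encoding(path) == enc

    def test_all_hash_is_phred33(self, tmp_path):
        # '#' = ASCII 35 < 59
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nACGT\n+\n####\n")
        assert detect_fastq_encoding(p) == "phred33"

    def test_all_h_is_phred64(self, tmp_path):
        # 'h' = ASCII 104 >= 64
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nACGT\n+\nhhhh\n")
        assert detect_fastq_encoding(p) == "phred64"

    def test_ambiguous_band_is_unknown(self, tmp_path):
        # 'I' = ASCII 73... no: 73 >= 64 would be phred64. Use ';' = 59..63 band
        p = tmp_path / "x.fastq"
        p.write_text("@r1\nACGT\n+\n;<=>\n")  # 59-62: ambiguous
        assert detect_fastq_encoding(p) == "unknown"

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "x.fastq.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("@r1\nACGT\n+\n!!!!\n")
        assert detect_fastq_encoding(p) == "phred33"

    def test_malformed_record_names_record_number(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\n!!!!\n@r2\nACGTACGT\n+\n!!\n")
        with pytest.raises(InputError, match="record 2"):
            detect_fastq_encoding(p)

    def test_sampling_agrees_with_whole_file_scan(self, tmp_path):
        (path,) = make_synthetic_fastq(tmp_path, sample="s", n_reads=30, seed=3)
        full = detect_fastq_encoding(path, sample_reads=10_000)
        sampled = detect_fastq_encoding(path, sample_reads=30)
        assert full == sampled


class TestMergeRegex:
    def test_lane_split_sample_merged(self):
        plan = apply_merge_regex(
            ["sample1_L001.fq.gz", "sample1_L002.fq.gz"], [r"(sample\d+)_L\d+"]
        )
        assert plan == {"sample1.fastq.gz": ["sample1_L001.fq.gz", "sample1_L002.fq.gz"]}

    def test_no_match_empty_plan(self):
        assert apply_merge_regex(["a.fq", "b.fq"], [r"(sample\d+)_L\d+"]) == {}

    def test_first_pattern_wins_on_overlap(self, caplog):
        with caplog.at_level("WARNING"):
            plan = apply_merge_regex(
                ["s1_L001.fq.gz"], [r"(s\d+)_L\d+", r"(s\d+_L\d+)"]
            )
        assert list(plan) == ["s1.fastq.gz"]

    def test_regex_without_capture_group_rejected(self):
        with pytest.raises(InputError, match="capture group"):
            apply_merge_regex(["a.fq"], [r"sample\d+_L\d+"])

    def test_merge_then_pair_equals_pair_of_merged(self, tmp_path):
        """Lane merging and pairing commute on lane-split paired samples."""
        files = []
        for lane in ("L001", "L002"):
            for read in ("R1", "R2"):
                p = tmp_path / f"samp_{lane}_{read}.fastq.gz"
                with gzip.open(p, "wt") as fh:
                    fh.write(f"@{lane}_{read}\nAC\n+\n!!\n")
                files.append(str(p))
        # captures keep the read token, so the pair structure survives merging
        plan = apply_merge_regex(files, [r"samp_L\d+_(R1)", r"samp_L\d+_(R2)"])
        plan = {f"samp_{t.split('.')[0]}.fastq.gz": s for t, s in plan.items()}
        merged = execute_merge(plan, out_dir=tmp_path)
        merged_groups = group_paired_files(sorted(merged))
        assert len(merged_groups) == 1 and merged_groups[0].is_paired
        # and each merged file concatenates both lanes
        for path in merged:
            with gzip.open(path, "rt") as fh:
                assert len(fh.read().splitlines()) == 8


class TestResolveInputs:
    def test_urls_become_download_jobs_pairable_by_basename(self):
        local, downloads = resolve_inputs(
            ["ftp://host/x_1.fastq.gz", "ftp://host/x_2.fastq.gz"]
        )
        assert local == []
        assert [d.filename for d in downloads] == ["x_1.fastq.gz", "x_2.fastq.gz"]
        groups = group_paired_files([d.filename for d in downloads])
        assert len(groups) == 1 and groups[0].is_paired

    def test_all_local_existing_no_downloads(self, tmp_path):
        f = tmp_path / "a.fq"
        f.write_text("@r\nA\n+\n!\n")
        local, downloads = resolve_inputs([str(f)])
        assert local == [str(f)] and downloads == []

    def test_missing_local_file_fatal_listing_it(self, tmp_path):
        with pytest.raises(InputError, match="ghost.fq"):
            resolve_inputs([str(tmp_path / "ghost.fq")])

    def test_unsupported_scheme_fatal(self):
        with pytest.raises(InputError, match="scheme"):
            resolve_inputs(["s3://bucket/x.fq"])
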