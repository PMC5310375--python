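"""Shared fixtures: stub toolbox on PATH, synthetic FastQ, base config."""

from __future__ import annotations

import os
import random

import pytest

from flowlite.config import load_config
from flowlite.pipeline import Pipeline, parse_pipeline
from flowlite.wrappers.stubs import make_stub_toolbox, make_synthetic_fastq


@pytest.fixture(scope="session")
def stub_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("stubs")
    make_stub_toolbox(d)
    return d


@pytest.fixture
def stub_path(stub_dir, monkeypatch):
    """Prepend the stub toolbox to PATH (visible to subprocesses too)."""
    monkeypatch.setenv("PATH", str(stub_dir) + os.pathsep + os.environ["PATH"])
    return stub_dir


@pytest.fixture
def base_config():
    return load_config([])


@pytest.fixture
def paired_groups(tmp_path):
    """Two synthetic paired-end samples, as the flat file list a user passes."""
    files = []
    for i, sample in enumerate(["alpha", "beta"]):
        files += [
            str(p)
            for p in make_synthetic_fastq(
                tmp_path / "data", sample=sample, n_reads=20, paired=True, seed=i
            )
        ]
    return files


def random_pipeline(rng: random.Random, max_depth: int = 5, max_branch: int = 4) -> Pipeline:
    """Random step tree for dependency-ordering properties."""
    counter = [0]

    def subtree(depth: int) -> list[str]:
        counter[0] += 1
        lines = ["\t" * depth + f"#mod{counter[0]}"]
        if depth + 1 < max_depth:
            for _ in range(rng.randint(0, max_branch - 1)):
                lines += subtree(depth + 1)
        return lines

    lines = []
    for _ in range(rng.randint(1, max_branch)):
        lines += subtree(0)
    return parse_pipeline("\n".join(lines) + "\n", name="rand")
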