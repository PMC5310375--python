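"""Packaged wrapper-module registry and command generation.

Wrapper modules are standalone executables discovered in ``modules/``
directories.  The packaged directory ships with the engine; site and user
directories may shadow packaged modules by name (the registry key is the
filename with its extension stripped).
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Mapping, Sequence

from ..helpers import FileGroup
from ..module_api import ResourceRequest
from .specs import BY_NAME, PACKAGED, WrapperSpec

__all__ = [
    "PACKAGED",
    "BY_NAME",
    "WrapperSpec",
    "WrapperError",
    "packaged_modules_dir",
    "module_registry",
    "list_packaged_modules",
    "generate_command",
    "outputs_for",
    "sample_stem",
]


class WrapperError(Exception):
    pass


def packaged_modules_dir() -> Path:
    return Path(__file__).resolve().parent.parent / "modules"


def module_registry(extra_dirs: Sequence[str | os.PathLike] = ()) -> dict[str, Path]:
    """Map module name -> wrapper path; later directories shadow earlier
    ones (packaged < site < user)."""
    registry: dict[str, Path] = {}
    for d in [packaged_modules_dir(), *map(Path, extra_dirs)]:
        if not Path(d).is_dir():
            continue
        for entry in sorted(Path(d).iterdir()):
            if entry.is_file() and not entry.name.startswith(("_", ".")):
                registry[entry.stem] = entry
    return registry


def list_packaged_modules() -> list[str]:
    """Sorted unique names of the wrapper modules shipped with the engine."""
    return sorted(s.stem for s in packaged_modules_dir().glob("*.py") if not s.name.startswith("_"))


# ---------------------------------------------------------------------------
# command generation

_EXTS = re.compile(
    r"(\.(fastq|fq|sam|bam|sra|txt|bedGraph|gtf))?(\.gz)?$", re.IGNORECASE
)
_READ_TOKENS = ("_R1", "_R2", "_1", "_2", ".1", ".2",
                "_trimmed", "_val_1", "_val_2")


def _stem(filename: str) -> str:
    base = os.path.basename(filename)
    m = _EXTS.search(base)
    return base[: m.start()] if m and m.group(0) else base


def sample_stem(filename: str) -> str:
    """Sample name for per-group outputs: extension stack and read tokens
    stripped (``x_R1.fastq.gz`` -> ``x``)."""
    stem = _stem(filename)
    changed = True
    while changed:
        changed = False
        for tok in _READ_TOKENS:
            if stem.endswith(tok) and len(stem) > len(tok):
                stem = stem[: -len(tok)]
                changed = True
    return stem


def outputs_for(spec: WrapperSpec, inputs: Sequence[str]) -> list[str]:
    """Declared output filenames for a step — a pure function of inputs."""
    if spec.out_mode == "none":
        return []
    if spec.out_mode == "per_input":
        return [_stem(f) + spec.out_suffix for f in inputs]
    if spec.out_mode == "per_group":
        return [sample_stem(inputs[0]) + spec.out_suffix] if inputs else []
    if spec.out_mode == "basename":
        return [os.path.basename(f.rstrip("/")) or "download" for f in inputs]
    raise WrapperError(f"{spec.name}: unknown out_mode {spec.out_mode!r}")


def _param_args(params: Sequence[str]) -> str:
    """Render pipeline/CLI params for the wrapped tool: ``key=value`` ->
    ``--key value``, bare ``flag`` -> ``--flag``; tokens already starting
    with ``-`` pass verbatim."""
    parts = []
    for p in params:
        if p.startswith("-"):
            parts.append(p)
        elif "=" in p:
            key, _, value = p.partition("=")
            parts += [f"--{key}", value]
        else:
            parts.append(f"--{p}")
    return " ".join(parts)


def generate_command(
    spec: WrapperSpec | str,
    group: FileGroup | Sequence[str],
    params: Sequence[str] = (),
    genome_paths: Mapping[str, str] | None = None,
    granted: ResourceRequest | None = None,
    inputs: Sequence[str] | None = None,
) -> list[str]:
    """Build the tool command line(s) for one job.

    Paired groups use the paired-end template, single groups the single-end
    one; a group layout the wrapper has no template for is fatal, as is a
    missing required genome reference.  Params are appended after the
    templated command (their documented insertion point).  Deterministic:
    same arguments, same strings.
    """
    if isinstance(spec, str):
        if spec not in BY_NAME:
            raise WrapperError(f"unknown packaged wrapper: {spec}")
        spec = BY_NAME[spec]
    if isinstance(group, FileGroup):
        files = list(inputs if inputs is not None else group.members)
        paired = group.is_paired
    else:
        files = list(group)
        paired = len(files) == 2 and bool(spec.paired)
    if not files:
        raise WrapperError(f"{spec.name}: no input files")

    genome_paths = genome_paths or {}
    genome = ""
    for ref_type in spec.required_ref_types:
        if ref_type not in genome_paths:
            raise WrapperError(
                f"module {spec.name} requires a {ref_type!r} genome reference "
                "but none was resolved"
            )
        if not genome:
            genome = genome_paths[ref_type]

    template = spec.paired if paired else spec.single
    if not template:
        layout = "paired-end" if paired else "single-end"
        raise WrapperError(f"module {spec.name} has no {layout} command template")

    granted = granted or ResourceRequest()
    outs = outputs_for(spec, files)
    fields = {
        "tool": spec.tool,
        "cores": granted.cores,
        "mem_mb": max(1, granted.memory // 2**20),
        "genome": genome,
        "inputs": " ".join(files),
        "input": files[0],
        "input1": files[0],
        "input2": files[1] if len(files) > 1 else "",
        "output": outs[0] if outs else "",
        "group": sample_stem(files[0]),
    }
    extra = _param_args(params)
    if (
        spec.out_mode == "per_input"
        and len(files) > 1
        and not any(ph in template for ph in ("{inputs}", "{input1}", "{input2}"))
    ):
        # template consumes one file at a time: one command per input
        cmds = []
        for f, out in zip(files, outs):
            per = dict(fields, inputs=f, input=f, input1=f, input2="", output=out)
            cmds.append(template.format(**per) + (f" {extra}" if extra else ""))
        return cmds
    if spec.out_mode == "basename":
        # download-style modules fetch each input separately
        cmds = []
        for f, out in zip(files, outs):
            per = dict(fields, inputs=f, input=f, input1=f, input2="", output=out)
            cmd = spec.single.format(**per)
            cmds.append(f"{cmd} {extra}" if extra else cmd)
        return cmds
    cmd = template.format(**fields)
    if extra:
        cmd = f"{cmd} {extra}"
    return [cmd]
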