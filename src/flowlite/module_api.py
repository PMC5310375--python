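"""Contract between the engine and standalone tool-wrapper executables.

At launch the engine asks every wrapper what it needs::

    <wrapper> --requirements --files <n> [--param k=v ...]

and the wrapper answers with ``key: value`` lines (``cores: 1-8``,
``memory: 4G``, ``time: 2h``, optionally ``time_per_file: true``,
``references: bowtie2``, ``modules: bowtie2/2.4``).  Requests are clamped
to the cluster limits from the config: the grant is the request's maximum
capped at the cluster maximum but never below the request's minimum; a
minimum exceeding the cluster maximum is fatal.  Per-file time is
multiplied by the file count and then capped.

At run time the wrapper is invoked with a deterministic argument template
(:func:`build_invocation`) and communicates back through greppable marker
lines on stdout::

    ###CF_OUT <filename>        an output file of this step
    ###CF_VERS <tool>:<version> a software version record
    ###CFCMD <command>          a command that was executed
    ###CF_ERR <message>         an error

Anything else is free log text and never breaks parsing.
"""

from __future__ import annotations

import re
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import ConfigSet


class ModuleProtocolError(Exception):
    """A wrapper violated the negotiation protocol (bad exit / bad output)."""


_MEM_SUFFIX = {"K": 2**10, "M": 2**20, "G": 2**30, "T": 2**40}


def parse_memory(text: str | int) -> int:
    """Parse ``4G``/``512M``/``1024`` into bytes (binary powers; bare
    integers are bytes)."""
    if isinstance(text, int):
        return text
    text = text.strip()
    m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*([KMGTkmgt])?[bB]?", text)
    if not m:
        raise ValueError(f"unparseable memory value: {text!r}")
    value = float(m.group(1))
    if m.group(2):
        value *= _MEM_SUFFIX[m.group(2).upper()]
    return int(value)


def format_memory(nbytes: int) -> str:
    for suffix, mult in (("T", 2**40), ("G", 2**30), ("M", 2**20), ("K", 2**10)):
        if nbytes % mult == 0 and nbytes >= mult:
            return f"{nbytes // mult}{suffix}"
    return str(nbytes)


def parse_time_minutes(text: str | int) -> int:
    """``90`` -> 90 min, ``2h`` -> 120, ``1d`` -> 1440, ``30m`` -> 30."""
    if isinstance(text, int):
        return text
    m = re.fullmatch(r"(\d+)\s*([mhd])?", text.strip())
    if not m:
        raise ValueError(f"unparseable time value: {text!r}")
    mult = {"m": 1, "h": 60, "d": 1440, None: 1}[m.group(2)]
    return int(m.group(1)) * mult


@dataclass
class ResourceRequest:
    """A wrapper's negotiated resource grant."""

    cores: int = 1
    memory: int = 1 * 2**30  # bytes
    time: int = 60  # minutes, after per-file resolution
    required_ref_types: list[str] = field(default_factory=list)
    environment_modules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cores < 1:
            raise ValueError("cores must be >= 1")
        if self.memory <= 0:
            raise ValueError("memory must be positive")
        if self.time < 1:
            raise ValueError("time must be >= 1 minute")


def _parse_range(text: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d+)(?:\s*-\s*(\d+))?", text.strip())
    if not m:
        raise ValueError(f"unparseable cores value: {text!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    return (min(lo, hi), max(lo, hi))


def negotiate(raw: dict[str, str], n_files: int, config: ConfigSet, module: str = "?") -> ResourceRequest:
    """Clamp a wrapper's raw ``key: value`` answers to the cluster limits."""
    lo, hi = _parse_range(raw.get("cores", "1"))
    cluster_max = config.max_cores
    if lo > cluster_max:
        raise ModuleProtocolError(
            f"module {module}: requires at least {lo} cores but cluster max is {cluster_max}"
        )
    cores = max(lo, min(hi, cluster_max))

    mem = parse_memory(raw.get("memory", "1G"))
    mem_max = config.max_mem_bytes
    if mem > mem_max:
        # memory requests are a single value; cap at the cluster limit
        mem = mem_max
    minutes = parse_time_minutes(raw.get("time", "60"))
    if raw.get("time_per_file", "").lower() in {"true", "1", "yes"}:
        minutes *= max(1, n_files)
    minutes = min(minutes, config.max_time_minutes)

    refs = [t for t in re.split(r"[,\s]+", raw.get("references", "")) if t]
    mods = [t for t in re.split(r"[,\s]+", raw.get("modules", "")) if t]
    return ResourceRequest(
        cores=cores,
        memory=mem,
        time=max(1, minutes),
        required_ref_types=refs,
        environment_modules=mods,
    )


def wrapper_argv(wrapper: str | Path, args: Sequence[str]) -> list[str]:
    """Argv for invoking a wrapper: run ``.py`` wrappers (and anything not
    marked executable) through the current interpreter."""
    wrapper = Path(wrapper)
    import os

    if wrapper.suffix == ".py" or not os.access(wrapper, os.X_OK):
        return [sys.executable, str(wrapper), *args]
    return [str(wrapper), *args]


def query_requirements(
    wrapper: str | Path,
    n_files: int,
    params: Sequence[str],
    config: ConfigSet,
    genome_id: str | None = None,
) -> ResourceRequest:
    """Run a wrapper in ``--requirements`` mode and negotiate its grant."""
    wrapper = Path(wrapper)
    if not wrapper.exists():
        raise ModuleProtocolError(f"module wrapper not found: {wrapper}")
    args = ["--requirements", "--files", str(n_files)]
    for p in params:
        args += ["--param", p]
    if genome_id:
        args += ["--genome_id", genome_id]
    try:
        proc = subprocess.run(
            wrapper_argv(wrapper, args), capture_output=True, text=True, timeout=60
        )
    except OSError as exc:
        raise ModuleProtocolError(f"module {wrapper.stem}: cannot execute wrapper: {exc}") from exc
    if proc.returncode != 0:
        raise ModuleProtocolError(
            f"module {wrapper.stem}: --requirements exited {proc.returncode}: "
            f"{proc.stderr.strip()[:500]}"
        )
    raw: dict[str, str] = {}
    for line in proc.stdout.splitlines():
        line = line.strip()
        if not line:
            continue
        key, sep, value = line.partition(":")
        if not sep or not key.strip():
            raise ModuleProtocolError(
                f"module {wrapper.stem}: unparseable requirements line {line!r}"
            )
        raw[key.strip().lower()] = value.strip()
    return negotiate(raw, n_files, config, module=wrapper.stem)


@dataclass(frozen=True)
class ModuleInvocation:
    """Concrete run-time call of a wrapper for one job."""

    wrapper: str
    runfile: str
    job_id: str
    prev_job_id: str  # ``start_000`` for first-step jobs
    cores: int
    memory: int
    params: tuple[str, ...] = ()
    genome_paths: tuple[str, ...] = ()  # ``ref_type=path`` pairs


def build_invocation(inv: ModuleInvocation) -> str:
    """Deterministic command line for a job (shell-quoted string)."""
    argv = [
        inv.wrapper,
        "--run_fn", inv.runfile,
        "--job_id", inv.job_id,
        "--prev_job_id", inv.prev_job_id,
        "--cores", str(inv.cores),
        "--mem", str(inv.memory),
    ]
    for p in inv.params:
        argv += ["--param", p]
    for g in inv.genome_paths:
        argv += ["--ref", g]
    return shlex.join(argv)


# ---------------------------------------------------------------------------
# marker grammar

MARKERS = {
    "###CF_OUT": "out",
    "###CF_VERS": "vers",
    "###CFCMD": "cmd",
    "###CF_ERR": "err",
}


@dataclass
class ModuleEmissions:
    outputs: list[str] = field(default_factory=list)
    versions: list[tuple[str, str]] = field(default_factory=list)
    commands: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    free_text: list[str] = field(default_factory=list)


def parse_module_emissions(lines: Sequence[str] | str) -> ModuleEmissions:
    """Extract ``###CF*`` marker records from module stdout.

    Order-preserving; unmarked lines are retained as free log text and never
    cause a failure.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    em = ModuleEmissions()
    for raw in lines:
        line = raw.rstrip("\n")
        stripped = line.strip()
        token, _, payload = stripped.partition(" ")
        kind = MARKERS.get(token)
        if kind == "out" and payload:
            em.outputs.append(payload.strip())
        elif kind == "vers" and payload:
            tool, _, version = payload.strip().partition(":")
            em.versions.append((tool, version))
        elif kind == "cmd" and payload:
            em.commands.append(payload.strip())
        elif kind == "err":
            em.errors.append(payload.strip())
        else:
            em.free_text.append(line)
    return em
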