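"""Pipeline definition language: hash-prefixed module steps, tab indentation.

A pipeline file looks like::

    @require_genome bowtie2
    #fastqc
    #trim_galore
    \t#bowtie2 q=1

Lines starting with ``#`` (after leading tabs) are module steps.  A step
indented one tab deeper than the nearest preceding step is its child and
runs *after* it (series); steps at equal depth under the same parent are
independent branches and may run in parallel.  Two consecutive root-level
steps are parallel branches — this dialect choice follows from indentation
being the only series marker.  ``@key value`` lines before the first step
are pipeline-level directives (for example a required genome reference
type).  Tokens after a module name are parameters passed to the module
verbatim, either bare flags or ``key=value``.

Depth is measured in tab characters only; leading spaces are a syntax
error, because silently mixing tabs and spaces produces pipelines that look
right and run wrong.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

MODULE_NAME_RE = re.compile(r"[A-Za-z0-9_]+$")


class PipelineSyntaxError(Exception):
    """Malformed pipeline text; message includes the line number."""


@dataclass
class ModuleStep:
    module_name: str
    params: list[str] = field(default_factory=list)
    depth: int = 0
    children: list["ModuleStep"] = field(default_factory=list)

    def walk(self) -> Iterator["ModuleStep"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Pipeline:
    name: str
    directives: dict[str, str] = field(default_factory=dict)
    roots: list[ModuleStep] = field(default_factory=list)

    def walk(self) -> Iterator[ModuleStep]:
        for root in self.roots:
            yield from root.walk()

    @property
    def n_steps(self) -> int:
        return sum(1 for _ in self.walk())


@dataclass(frozen=True)
class PlannedJob:
    """Skeleton of one scheduler job: a step instantiated for one group."""

    name: str
    module_name: str
    params: tuple[str, ...]
    group: int
    upstream: str | None  # name of the parent step's job for the same group


@dataclass
class JobPlan:
    jobs: list[PlannedJob]
    edges: list[tuple[str, str]]  # (upstream name, downstream name)


def parse_pipeline(text: str, name: str = "pipeline") -> Pipeline:
    """Parse pipeline text into a step tree.

    Raises :class:`PipelineSyntaxError` on depth jumps >= 2, indented steps
    before any root, leading spaces, or unknown leading characters.
    """
    if not text.strip():
        raise PipelineSyntaxError("empty pipeline definition")
    pipe = Pipeline(name=name)
    stack: list[ModuleStep] = []  # stack[d] = most recent step at depth d
    seen_step = False
    for lineno, raw in enumerate(text.replace("\r\n", "\n").splitlines(), start=1):
        if not raw.strip():
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        body = raw[depth:]
        if body.startswith(" "):
            raise PipelineSyntaxError(
                f"line {lineno}: leading spaces are not allowed (indent with tabs)"
            )
        if body.startswith("@"):
            if seen_step:
                raise PipelineSyntaxError(
                    f"line {lineno}: directives must precede the first module step"
                )
            key, _, value = body[1:].partition(" ")
            pipe.directives[key] = value.strip()
            continue
        if not body.startswith("#"):
            raise PipelineSyntaxError(
                f"line {lineno}: expected '#module' step or '@key value' directive, got {body!r}"
            )
        tokens = body[1:].split()
        if not tokens:
            raise PipelineSyntaxError(f"line {lineno}: '#' with no module name")
        module_name, params = tokens[0], tokens[1:]
        if not MODULE_NAME_RE.match(module_name):
            raise PipelineSyntaxError(
                f"line {lineno}: invalid module name {module_name!r}"
            )
        step = ModuleStep(module_name=module_name, params=params, depth=depth)
        if depth == 0:
            pipe.roots.append(step)
            stack = [step]
        else:
            if not seen_step:
                raise PipelineSyntaxError(
                    f"line {lineno}: indented step before any root-level step"
                )
            if depth > len(stack):
                prev_depth = len(stack) - 1
                raise PipelineSyntaxError(
                    f"line {lineno}: indentation jumps from depth {prev_depth} to {depth}"
                )
            parent = stack[depth - 1]
            parent.children.append(step)
            del stack[depth:]
            stack.append(step)
        seen_step = True
    if not pipe.roots:
        raise PipelineSyntaxError("pipeline defines no module steps")
    return pipe


def render_pipeline(pipe: Pipeline) -> str:
    """Inverse of :func:`parse_pipeline` (modulo blank lines / comments)."""
    lines = [f"@{k} {v}".rstrip() for k, v in pipe.directives.items()]

    def emit(step: ModuleStep) -> None:
        params = (" " + " ".join(step.params)) if step.params else ""
        lines.append("\t" * step.depth + f"#{step.module_name}{params}")
        for child in step.children:
            emit(child)

    for root in pipe.roots:
        emit(root)
    return "\n".join(lines) + "\n"


def plan_jobs(pipe: Pipeline, n_groups: int, run_id: str = "run") -> JobPlan:
    """Instantiate the step tree once per input group.

    One job per (step x group); a job depends only on its parent step's job
    for the *same* group, so groups never wait on each other.  Jobs are
    emitted in topological (depth-first) order within each group.  Names
    follow ``cf_<pipeline>_<runid>_<module>_<group>``, with an ordinal
    suffix only where a module recurs in the tree and would collide.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    if not pipe.roots:
        raise ValueError("cannot plan jobs for an empty pipeline")
    jobs: list[PlannedJob] = []
    edges: list[tuple[str, str]] = []
    for group in range(n_groups):
        used: set[str] = set()

        def visit(step: ModuleStep, upstream: str | None) -> None:
            base = f"cf_{pipe.name}_{run_id}_{step.module_name}_{group}"
            name, k = base, 1
            while name in used:
                name = f"{base}_{k}"
                k += 1
            used.add(name)
            jobs.append(
                PlannedJob(
                    name=name,
                    module_name=step.module_name,
                    params=tuple(step.params),
                    group=group,
                    upstream=upstream,
                )
            )
            if upstream is not None:
                edges.append((upstream, name))
            for child in step.children:
                visit(child, name)

        for root in pipe.roots:
            visit(root, None)
    return JobPlan(jobs=jobs, edges=edges)


def validate_pipeline(pipe: Pipeline, registry: Sequence[str], genome_id: str | None = None) -> list[str]:
    """Return a list of problems (empty = valid); never raises.

    Checks unknown module names (with a nearest-match hint), duplicate
    sibling names, and a ``require_genome`` directive unsatisfied because no
    genome was given on the command line.
    """
    import difflib

    problems: list[str] = []
    known = set(registry)
    for step in pipe.walk():
        if step.module_name not in known:
            hint = difflib.get_close_matches(step.module_name, registry, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            problems.append(f"unknown module {step.module_name!r}{suffix}")

    def check_siblings(steps: list[ModuleStep]) -> None:
        seen: set[str] = set()
        for s in steps:
            if s.module_name in seen:
                problems.append(f"duplicate sibling step {s.module_name!r}")
            seen.add(s.module_name)
            check_siblings(s.children)

    check_siblings(pipe.roots)
    if pipe.directives.get("require_genome") and genome_id is None:
        problems.append(
            "pipeline requires a genome reference "
            f"({pipe.directives['require_genome']}) but no --genome was given"
        )
    return problems
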