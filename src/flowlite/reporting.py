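"""Run-log parsing and completion reports.

When a pipeline finishes, its log files (every wrapper's stdout, including
``###CF*`` marker lines) are parsed into typed events and rendered as a
plain-text and a self-contained HTML report.  Errors are surfaced first —
before any step detail — in both renderings, so a failed run is obvious
from the first lines of the notification.

The default "e-mail" sender is a file sender: it writes ``.email.txt`` and
``.email.html`` next to the run file.  Real delivery is behind the
:class:`ReportSender` interface so deployments can plug in SMTP without the
engine knowing about it.
"""

from __future__ import annotations

import getpass
import html
import os
import platform
import re
from dataclasses import dataclass, field
from pathlib import Path
from string import Template
from typing import Protocol, Sequence

from .config import ConfigSet
from .runfile import RunFileData


@dataclass(frozen=True)
class RunEvent:
    kind: str  # start | end | command | version | error | out | info
    payload: str
    job_id: str = ""
    timestamp: str = ""


_MARK_RE = re.compile(
    r"^(?P<marker>###CF_START|###CF_END|###CFCMD|###CF_VERS|###CF_ERR|###CF_OUT)\s*(?P<rest>.*)$"
)

_KIND = {
    "###CF_START": "start",
    "###CF_END": "end",
    "###CFCMD": "command",
    "###CF_VERS": "version",
    "###CF_ERR": "error",
    "###CF_OUT": "out",
}


def parse_run_log(text: str) -> list[RunEvent]:
    """Typed events in file order; unmarked lines become ``info`` events.

    Never fails: arbitrary tool chatter is just info.
    """
    events: list[RunEvent] = []
    for raw in text.splitlines():
        m = _MARK_RE.match(raw.strip())
        if not m:
            events.append(RunEvent(kind="info", payload=raw))
            continue
        kind = _KIND[m.group("marker")]
        rest = m.group("rest").strip()
        if kind in {"start", "end"}:
            parts = rest.split()
            job = parts[0] if parts else ""
            stamp = parts[1] if len(parts) > 1 else ""
            events.append(RunEvent(kind=kind, payload=rest, job_id=job, timestamp=stamp))
        else:
            events.append(RunEvent(kind=kind, payload=rest))
    return events


@dataclass
class RunReport:
    run_id: str
    outcome: str  # "success" | "errors"
    errors: list[str] = field(default_factory=list)
    commands: list[str] = field(default_factory=list)
    versions: dict[str, str] = field(default_factory=dict)  # tool -> latest seen
    durations: list[tuple[str, float]] = field(default_factory=list)  # (job, seconds)
    working_dir: str = ""
    malformed: bool = False
    info_lines: int = 0


def build_report(events: Sequence[RunEvent], runfile: RunFileData | None = None) -> RunReport:
    """Aggregate events; outcome is ``errors`` iff any error event exists.

    Versions deduplicate per tool (latest seen wins).  Per-step durations
    come from matched start/end pairs; an end with no earlier start flags
    the report as malformed, but it still renders.
    """
    import datetime as _dt

    report = RunReport(
        run_id=runfile.header.run_id if runfile else "",
        outcome="success",
        working_dir=str(runfile.path.parent) if runfile else "",
    )
    starts: dict[str, str] = {}
    for ev in events:
        if ev.kind == "error":
            report.errors.append(ev.payload)
        elif ev.kind == "command":
            report.commands.append(ev.payload)
        elif ev.kind == "version":
            tool, _, version = ev.payload.partition(":")
            if tool:
                report.versions[tool] = version
        elif ev.kind == "start":
            starts[ev.job_id] = ev.timestamp
        elif ev.kind == "end":
            if ev.job_id not in starts:
                report.malformed = True
                continue
            t0, t1 = starts.pop(ev.job_id), ev.timestamp
            try:
                seconds = (
                    _dt.datetime.fromisoformat(t1) - _dt.datetime.fromisoformat(t0)
                ).total_seconds()
            except ValueError:
                seconds = 0.0
            report.durations.append((ev.job_id, seconds))
        elif ev.kind == "info":
            report.info_lines += 1
    if report.errors:
        report.outcome = "errors"
    return report


_RULE = "-" * 78


def render_text(report: RunReport) -> str:
    """Plain ASCII report, <= 100 columns, errors first."""
    lines: list[str] = []
    title = (
        "Pipeline completed successfully"
        if report.outcome == "success"
        else "Pipeline completed with ERRORS"
    )
    lines += [_RULE, f"Cluster Flow run report: {report.run_id or '(unnamed run)'}", title, _RULE]
    if report.errors:
        lines.append("")
        lines.append("ERRORS (%d):" % len(report.errors))
        for err in report.errors:
            lines.append(f"  !! {err}"[:100])
    if report.malformed:
        lines.append("")
        lines.append("WARNING: log was malformed (unmatched job end markers)")
    if report.working_dir:
        lines += ["", f"Working directory: {report.working_dir}"]
    if report.durations:
        lines += ["", "Step durations:"]
        for job, secs in report.durations:
            lines.append(f"  {job}: {secs:.0f}s"[:100])
    if report.commands:
        import textwrap

        lines += ["", "Commands executed (%d):" % len(report.commands)]
        for cmd in report.commands:
            # wrap, never truncate: the report must list each command whole
            wrapped = textwrap.wrap("$ " + cmd, width=96, subsequent_indent="    ",
                                    break_on_hyphens=False)
            lines += ["  " + w for w in wrapped]
    if report.versions:
        lines += ["", "Software versions:"]
        for tool in sorted(report.versions):
            lines.append(f"  {tool}: {report.versions[tool]}"[:100])
    lines.append("")
    return "\n".join(lines) + "\n"


_HTML_TMPL = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Run report: $run_id</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
.banner { padding: 0.8em 1em; border-radius: 4px; font-weight: bold; }
.ok { background: #dff0d8; color: #3c763d; }
.bad { background: #f2dede; color: #a94442; }
.error { background: #f2dede; padding: 0.4em 0.8em; margin: 0.3em 0; border-radius: 3px; }
pre.cmd { background: #f5f5f5; padding: 0.5em; overflow-x: auto; }
table { border-collapse: collapse; }
td, th { border: 1px solid #ccc; padding: 0.3em 0.8em; text-align: left; }
</style></head>
<body>
<h1>Cluster Flow run report: $run_id</h1>
<div class="banner $banner_class">$banner</div>
$errors_html
$body_html
</body></html>
"""
)


def render_html(report: RunReport) -> str:
    """Single self-contained HTML document (inline styles), errors first."""
    esc = html.escape
    if report.outcome == "success":
        banner, banner_class = "Pipeline completed successfully", "ok"
    else:
        banner, banner_class = "Pipeline completed with ERRORS", "bad"
    errors_html = ""
    if report.errors:
        rows = "\n".join(f'<div class="error">{esc(e)}</div>' for e in report.errors)
        errors_html = f"<h2>Errors ({len(report.errors)})</h2>\n{rows}"
    if report.malformed:
        errors_html += '\n<div class="error">Log was malformed (unmatched end markers)</div>'
    body: list[str] = []
    if report.working_dir:
        body.append(f"<p>Working directory: <code>{esc(report.working_dir)}</code></p>")
    if report.durations:
        rows = "\n".join(
            f"<tr><td>{esc(j)}</td><td>{s:.0f}s</td></tr>" for j, s in report.durations
        )
        body.append(f"<h2>Step durations</h2>\n<table><tr><th>Job</th><th>Duration</th></tr>{rows}</table>")
    if report.commands:
        blocks = "\n".join(f'<pre class="cmd">{esc(c)}</pre>' for c in report.commands)
        body.append(f"<h2>Commands executed ({len(report.commands)})</h2>\n{blocks}")
    if report.versions:
        rows = "\n".join(
            f"<tr><td>{esc(t)}</td><td>{esc(v)}</td></tr>"
            for t, v in sorted(report.versions.items())
        )
        body.append(f"<h2>Software versions</h2>\n<table><tr><th>Tool</th><th>Version</th></tr>{rows}</table>")
    return _HTML_TMPL.substitute(
        run_id=esc(report.run_id or "(unnamed run)"),
        banner=banner,
        banner_class=banner_class,
        errors_html=errors_html,
        body_html="\n".join(body),
    )


def write_versions_file(report: RunReport, path: str | os.PathLike) -> None:
    """Sidecar ``*_versions.txt``: one ``tool<TAB>version`` line per tool."""
    with open(path, "w") as fh:
        for tool in sorted(report.versions):
            fh.write(f"{tool}\t{report.versions[tool]}\n")


# ---------------------------------------------------------------------------
# submission log


def write_submission_log(config: ConfigSet, env: dict[str, str] | None = None) -> str:
    """System-information block recorded when a pipeline is submitted:
    search PATH, user, loaded environment modules, platform, and the full
    resolved configuration (including e-mail addresses — the submission log
    is a local file owned by the submitting user)."""
    env = dict(os.environ) if env is None else env
    try:
        user = getpass.getuser()
    except Exception:  # pragma: no cover
        user = env.get("USER", "unknown")
    modules = env.get("LOADEDMODULES", "").replace(":", " ").strip() or "none"
    lines = [
        "== Submission environment ==",
        f"PATH: {env.get('PATH', '')}",
        f"user: {user}",
        f"environment modules: {modules}",
        f"sysinfo: {platform.platform()} python/{platform.python_version()}",
        "== Resolved configuration ==",
    ]
    for key in config.entries:
        for val in config.get_all(key):
            lines.append(f"@{key} {val}  (from {config.provenance.get(key, '?')})")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# senders


class ReportSender(Protocol):
    def send(self, report: RunReport, text: str, html_doc: str) -> None: ...


class FileSender:
    """Default sender: writes the would-be e-mail next to the run file."""

    def __init__(self, directory: str | os.PathLike, recipient: str = ""):
        self.directory = Path(directory)
        self.recipient = recipient

    def send(self, report: RunReport, text: str, html_doc: str) -> None:
        stem = report.run_id or "run"
        header = f"To: {self.recipient}\n" if self.recipient else ""
        (self.directory / f"{stem}.email.txt").write_text(header + text)
        (self.directory / f"{stem}.email.html").write_text(html_doc)
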