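"""Detached local-run worker: ``python -m flowlite._localworker plan.json``.

The plan file is JSON written by the CLI when ``--local --background`` is
requested: the serialized local jobs, the run-file paths and the
notification address.  The worker replays the plan through the serial
executor and writes the completion reports; all state lands in the run
files, so the launching process exits immediately after detaching.
"""

from __future__ import annotations

import json
import sys

from .launch import write_reports
from .scheduler import LocalJob, run_local


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: python -m flowlite._localworker <plan.json>", file=sys.stderr)
        return 2
    with open(argv[0]) as fh:
        raw = json.load(fh)
    jobs = [LocalJob(**item) for item in raw["jobs"]]
    results = run_local(jobs, max_parallel_groups=raw.get("max_parallel_groups", 2))
    group_of = {j.name: j.group for j in jobs}
    write_reports(raw.get("runfiles", []), results, group_of, email=raw.get("email", ""))
    return 0 if all(r.status == "ok" for r in results.values()) else 1


if __name__ == "__main__":
    raise SystemExit(main())
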