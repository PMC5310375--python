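"""Synthetic test fixtures: stub tool executables and generated FastQ.

``make_stub_toolbox`` writes one small executable per tool wrapped by the
packaged modules.  A stub echoes its argument vector, answers any version
probe with a fixed fake version, honours a ``--fail`` flag by exiting
nonzero, and creates the output files the calling wrapper declared through
the ``CF_STUB_OUTPUTS`` environment variable (gzipped files get a minimal
valid FastQ record; everything else gets one text line).  With the stub
directory prepended to ``PATH``, entire packaged pipelines run end to end
on a machine with no bioinformatics tools installed.

``make_synthetic_fastq`` writes deterministic gzipped FastQ with a chosen
phred encoding, single or paired — the study input for every end-to-end
exercise of the engine.
"""

from __future__ import annotations

import gzip
import os
import random
import stat
import sys
from pathlib import Path
from .specs import PACKAGED

_STUB_TEMPLATE = '''#!{python}
"""Stub for the {tool!r} executable (synthetic test fixture)."""
import gzip, os, sys

TOOL = {tool!r}
_FAKE_FASTQ = b"@stub_read_1\\nACGT\\n+\\nIIII\\n"

def main():
    args = sys.argv[1:]
    if any(a in ("--version", "-v", "-V", "-version", "version") for a in args):
        print("%s 0.0.1-stub" % TOOL)
        return 0
    sys.stdout.write("stub %s argv: %s\\n" % (TOOL, " ".join(args)))
    if "--fail" in args:
        sys.stderr.write("stub %s failing as requested\\n" % TOOL)
        return 1
    for out in os.environ.get("CF_STUB_OUTPUTS", "").split(os.pathsep):
        if not out:
            continue
        if out.endswith(".gz"):
            with gzip.open(out, "wb") as fh:
                fh.write(_FAKE_FASTQ)
        else:
            with open(out, "w") as fh:
                fh.write("stub output of %s\\n" % TOOL)
    return 0

if __name__ == "__main__":
    sys.exit(main())
'''


def make_stub_toolbox(directory: str | os.PathLike) -> dict[str, Path]:
    """Create stub executables for every packaged wrapper's tool.

    Returns tool name -> stub path.  Prepend *directory* to ``PATH`` to make
    the engine pick them up.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stubs: dict[str, Path] = {}
    for spec in PACKAGED:
        if spec.tool in stubs:
            continue
        path = directory / spec.tool
        path.write_text(_STUB_TEMPLATE.format(python=sys.executable, tool=spec.tool))
        path.chmod(path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
        stubs[spec.tool] = path
    return stubs


_BASES = "ACGT"


def make_synthetic_fastq(
    out_dir: str | os.PathLike,
    sample: str = "sample",
    n_reads: int = 100,
    read_len: int = 50,
    encoding: str = "phred33",
    paired: bool = False,
    seed: int = 0,
) -> list[Path]:
    """Write deterministic gzipped FastQ for one synthetic sample.

    Quality characters are drawn uniformly from the encoding's legal band:
    phred33 uses ASCII 33-58 (so the minimum always falls below the 59
    detection threshold), phred64 uses ASCII 64-104.  Paired mode writes
    ``<sample>_R1`` / ``<sample>_R2`` with identical read ids per index.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if encoding == "phred33":
        q_lo, q_hi = 33, 58
    elif encoding == "phred64":
        q_lo, q_hi = 64, 104
    else:
        raise ValueError(f"encoding must be phred33 or phred64, got {encoding!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    reads = []
    for i in range(n_reads):
        seq = "".join(rng.choice(_BASES) for _ in range(read_len))
        qual = "".join(chr(rng.randint(q_lo, q_hi)) for _ in range(read_len))
        reads.append((f"@{sample}_read_{i}", seq, qual))
    paths: list[Path] = []
    mates = ("_R1", "_R2") if paired else ("",)
    for mate in mates:
        path = out_dir / f"{sample}{mate}.fastq.gz"
        # mtime=0 so identical seeds give byte-identical files
        with open(path, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as fh:
            for rid, seq, qual in reads:
                fh.write(f"{rid}\n{seq}\n+\n{qual}\n".encode())
        paths.append(path)
    return paths
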