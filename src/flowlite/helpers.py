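"""Input intelligence: paired-end grouping, FastQ quality-encoding
detection, regex-driven lane merging, and URL inputs.

These helpers are what make launches "just work": users point the engine at
a directory of FastQ files and the right per-sample groups fall out, with
paired-end command variants triggered automatically.
"""

from __future__ import annotations

import gzip
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence
from urllib.parse import urlparse

log = logging.getLogger(__name__)

# Read-pair tokens in precedence order: the token must appear immediately
# before the extension stack (.fastq.gz etc.) or a separator.  _R1/_R2 is
# the modern Illumina convention and is tried first.
PAIR_TOKENS: tuple[tuple[str, str], ...] = (
    ("_R1", "_R2"),
    ("_1", "_2"),
    (".1", ".2"),
)

_EXT_RE = re.compile(r"(\.(fastq|fq|txt|sra))?(\.gz)?$", re.IGNORECASE)


class InputError(Exception):
    pass


@dataclass
class FileGroup:
    """One sample's files: a single FastQ or an ordered (R1, R2) pair."""

    group_id: str
    members: list[str]
    layout: str  # "single" | "paired"
    merged_from: dict[str, list[str]] = field(default_factory=dict)

    @property
    def is_paired(self) -> bool:
        return self.layout == "paired"


def _split_ext(name: str) -> tuple[str, str]:
    base = os.path.basename(name)
    m = _EXT_RE.search(base)
    if m and m.group(0):
        return base[: m.start()], m.group(0)
    return base, ""


def _pair_key(filename: str) -> tuple[str, int, str] | None:
    """(sample stem, read number, token pair id) if a read token is found."""
    stem, _ext = _split_ext(filename)
    for tok1, tok2 in PAIR_TOKENS:
        for read, tok in ((1, tok1), (2, tok2)):
            if stem.endswith(tok):
                return stem[: -len(tok)], read, tok1
    return None


def group_paired_files(filenames: Sequence[str]) -> list[FileGroup]:
    """Partition files into paired/single groups by read-token matching.

    Files whose names differ only by a read token pair up; everything else
    is a single-end group.  An ``_R2`` with no ``_R1`` partner is demoted to
    single with a warning.  Output is sorted by group id, so repeated
    launches see identical grouping.
    """
    if not filenames:
        raise InputError("no input files given")
    pending: dict[tuple[str, str, str], dict[int, str]] = {}
    singles: list[str] = []
    for name in filenames:
        key = _pair_key(name)
        if key is None:
            singles.append(name)
            continue
        sample, read, token = key
        slot = pending.setdefault((os.path.dirname(name), sample, token), {})
        if read in slot:
            log.warning("duplicate read-%d file for sample %r: %s", read, sample, name)
            singles.append(name)
        else:
            slot[read] = name

    groups: list[FileGroup] = []
    for (_dir, sample, _token), reads in pending.items():
        if 1 in reads and 2 in reads:
            groups.append(FileGroup(sample, [reads[1], reads[2]], "paired"))
        else:
            read, name = next(iter(reads.items()))
            if read == 2:
                log.warning("read-2 file %s has no read-1 partner; treated as single-end", name)
            stem, _ = _split_ext(name)
            groups.append(FileGroup(stem, [name], "single"))
    for name in singles:
        stem, _ = _split_ext(name)
        groups.append(FileGroup(stem, [name], "single"))
    groups.sort(key=lambda g: (g.group_id, g.members))
    return groups


# ---------------------------------------------------------------------------
# FastQ encoding detection


def _open_maybe_gzip(path: str | os.PathLike) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def detect_fastq_encoding(path: str | os.PathLike, sample_reads: int = 1000) -> str:
    """Classify quality encoding by the minimum observed quality character.

    min ASCII < 59  -> ``phred33`` (Sanger / Illumina 1.8+; qualities start
    at ``!`` = 33 and legacy encodings never dip below ``;`` = 59);
    min ASCII >= 64 -> ``phred64`` (Illumina 1.3-1.5);
    anything between is ambiguous -> ``unknown`` (callers proceed with a
    logged phred33 assumption).
    """
    min_q = 256
    with _open_maybe_gzip(path) as fh:
        for record in range(sample_reads):
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise InputError(f"{path}: malformed FastQ at record {record + 1}")
            if len(seq) != len(qual):
                raise InputError(
                    f"{path}: record {record + 1}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            if qual:
                min_q = min(min_q, min(ord(c) for c in qual))
    if min_q == 256:
        return "unknown"
    if min_q < 59:
        return "phred33"
    if min_q >= 64:
        return "phred64"
    return "unknown"


# ---------------------------------------------------------------------------
# merge regexes


def apply_merge_regex(
    filenames: Sequence[str], patterns: Sequence[str]
) -> dict[str, list[str]]:
    """Plan lane merges: files whose single capture group matches the same
    sample id are concatenated into ``<capture>.fastq.gz``.

    The first pattern to match a file claims it; later patterns see only
    unclaimed files.  Non-matching files are untouched (absent from the
    plan).  A regex without exactly one capture group is a config error.
    """
    compiled = []
    for pat in patterns:
        rx = re.compile(pat)
        if rx.groups != 1:
            raise InputError(
                f"merge regex must have exactly one capture group: {pat!r} has {rx.groups}"
            )
        compiled.append(rx)
    plan: dict[str, list[str]] = {}
    claimed: set[str] = set()
    for idx, rx in enumerate(compiled):
        for name in filenames:
            if name in claimed:
                if rx.search(os.path.basename(name)):
                    log.warning(
                        "file %s also matches merge pattern #%d; first pattern wins", name, idx + 1
                    )
                continue
            m = rx.search(os.path.basename(name))
            if m:
                target = f"{m.group(1)}.fastq.gz"
                plan.setdefault(target, []).append(name)
                claimed.add(name)
    for target in plan:
        plan[target].sort()
    # merging a single file is a rename-by-concatenation; keep it in the plan
    return dict(sorted(plan.items()))


def execute_merge(plan: dict[str, list[str]], out_dir: str | os.PathLike = ".") -> list[str]:
    """Concatenate gzip members (gzip streams are concatenable) per target."""
    out_paths = []
    for target, sources in plan.items():
        out = Path(out_dir) / target
        with open(out, "wb") as dst:
            for src in sources:
                with open(src, "rb") as s:
                    while chunk := s.read(1 << 20):
                        dst.write(chunk)
        out_paths.append(str(out))
    return out_paths


# ---------------------------------------------------------------------------
# URL inputs


@dataclass(frozen=True)
class DownloadJob:
    url: str
    filename: str  # URL basename; the download module fetches to this name


SUPPORTED_SCHEMES = {"http", "https", "ftp"}


def resolve_inputs(args: Sequence[str]) -> tuple[list[str], list[DownloadJob]]:
    """Split mixed paths/URLs into validated local paths and download jobs.

    Each URL contributes its basename to the input list (so pairing sees
    ``x_1.fastq.gz``) plus a download job prepended to its group's plan.
    Missing local files and unsupported URL schemes are fatal before any
    submission happens.
    """
    local: list[str] = []
    downloads: list[DownloadJob] = []
    missing: list[str] = []
    for arg in args:
        parsed = urlparse(arg)
        if parsed.scheme and parsed.netloc:
            if parsed.scheme not in SUPPORTED_SCHEMES:
                raise InputError(f"unsupported URL scheme {parsed.scheme!r}: {arg}")
            basename = os.path.basename(parsed.path) or "download"
            downloads.append(DownloadJob(url=arg, filename=basename))
        else:
            if not Path(arg).exists():
                missing.append(arg)
            else:
                local.append(arg)
    if missing:
        raise InputError("input file(s) not found: " + ", ".join(missing))
    return local, downloads
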