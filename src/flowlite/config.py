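"""Layered key-value configuration and reference-genome management.

Configuration files are plain text, one ``@key value`` entry per line, with
``#`` comments.  Files are loaded in precedence order (site -> user ->
project -> command line); later files override earlier ones key by key,
except for *repeatable* keys (``@merge_regex``) which accumulate across all
layers.  Provenance (which file supplied the winning value) is tracked per
key.

Reference genomes live in a separate file, one record per line::

    genome_id<TAB>ref_type<TAB>path[<TAB>species<TAB>assembly]

so that a single assembly ID can map to several reference types (a FASTA, a
bowtie2 index prefix, a STAR index directory, ...).  Paths are stored
verbatim; wrapper modules decide how to interpret them.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: keys that accumulate across config layers instead of overriding
REPEATABLE_KEYS = frozenset({"merge_regex"})

#: built-in defaults used when no config file mentions a key
DEFAULTS: Mapping[str, str] = {
    "cluster_environment": "local",
    "max_cores": "8",
    "max_mem": "32G",
    "max_time": "10080",  # minutes (7 days)
    "split_files": "1",
}


class ConfigError(Exception):
    """Fatal configuration problem (unreadable file, duplicate genome, ...)."""


@dataclass
class ConfigSet:
    """Merged key-value options with per-key provenance.

    ``entries`` maps option name to a string, or to a list of strings for
    repeatable keys.  ``provenance`` names the file that supplied the winning
    value (``"<defaults>"`` / ``"<cli>"`` for synthetic layers).
    """

    entries: dict[str, str | list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def get(self, key: str, default: str | None = None) -> str | None:
        val = self.entries.get(key, default)
        if isinstance(val, list):  # repeatable key: callers wanting all use get_all
            return val[-1] if val else default
        return val

    def get_all(self, key: str) -> list[str]:
        val = self.entries.get(key)
        if val is None:
            return []
        return list(val) if isinstance(val, list) else [val]

    def set(self, key: str, value: str, source: str = "<cli>") -> None:
        if key in REPEATABLE_KEYS:
            self.entries.setdefault(key, [])
            assert isinstance(self.entries[key], list)
            self.entries[key].append(value)  # type: ignore[union-attr]
        else:
            self.entries[key] = value
        self.provenance[key] = source

    # -- cluster limits ----------------------------------------------------

    @property
    def max_cores(self) -> int:
        return int(self.get("max_cores", DEFAULTS["max_cores"]))

    @property
    def max_mem_bytes(self) -> int:
        from .module_api import parse_memory

        return parse_memory(self.get("max_mem", DEFAULTS["max_mem"]))

    @property
    def max_time_minutes(self) -> int:
        return int(self.get("max_time", DEFAULTS["max_time"]))

    def serialize(self) -> str:
        """Render back to ``@key value`` text; round-trips through load."""
        lines = []
        for key in self.entries:
            for val in self.get_all(key):
                lines.append(f"@{key} {val}")
        return "\n".join(lines) + "\n"


def load_config(
    paths: Sequence[str | os.PathLike],
    optional: bool = True,
    defaults: Mapping[str, str] = DEFAULTS,
) -> ConfigSet:
    """Merge config files in order; later files win key by key.

    Missing files are skipped silently when *optional* (the usual layering
    case: a user may have no project config).  An existing but unreadable
    file is fatal.  Malformed lines are skipped with a warning; unknown keys
    are retained so wrappers can define their own options.
    """
    cfg = ConfigSet()
    for key, val in defaults.items():
        cfg.set(key, val, source="<defaults>")
    for path in paths:
        path = Path(path)
        if not path.exists():
            if optional:
                continue
            raise ConfigError(f"config file not found: {path}")
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not line.startswith("@"):
                log.warning("%s:%d: malformed config line skipped: %r", path, lineno, raw)
                continue
            key, _, value = line[1:].partition(" ")
            if not key:
                log.warning("%s:%d: empty key skipped", path, lineno)
                continue
            cfg.set(key, value.strip(), source=str(path))
    return cfg


def default_config_paths() -> list[Path]:
    """Site config (beside the installed package, overridable via env) then
    user config then per-directory project config."""
    candidates = []
    site = os.environ.get("FLOWLITE_SITE_CONFIG")
    if site:
        candidates.append(Path(site))
    candidates.append(Path.home() / ".flowlite" / "flowlite.config")
    candidates.append(Path.cwd() / "flowlite.config")
    return candidates


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class GenomeRef:
    """One reference: (genome_id, ref_type) -> verbatim path prefix."""

    genome_id: str
    ref_type: str
    path: str
    species: str = ""
    assembly: str = ""


def load_genomes(path: str | os.PathLike) -> list[GenomeRef]:
    """Parse a genome config file; missing file means no genomes."""
    path = Path(path)
    if not path.exists():
        return []
    refs: list[GenomeRef] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            log.warning("%s:%d: malformed genome line skipped: %r", path, lineno, raw)
            continue
        species = fields[3] if len(fields) > 3 else ""
        assembly = fields[4] if len(fields) > 4 else ""
        ref = GenomeRef(fields[0], fields[1], fields[2], species, assembly)
        key = (ref.genome_id, ref.ref_type)
        if key in seen:
            log.warning("%s:%d: duplicate genome entry %s ignored", path, lineno, key)
            continue
        seen.add(key)
        refs.append(ref)
    return refs


def add_genome(
    config_path: str | os.PathLike,
    genome_id: str,
    ref_type: str,
    path: str,
    species: str = "",
    assembly: str = "",
) -> GenomeRef:
    """Append one reference record; duplicates of (id, type) are an error."""
    config_path = Path(config_path)
    existing = load_genomes(config_path)
    for ref in existing:
        if ref.genome_id == genome_id and ref.ref_type == ref_type:
            raise ConfigError(
                f"genome ({genome_id}, {ref_type}) already defined in {config_path} "
                f"with path {ref.path}"
            )
    config_path.parent.mkdir(parents=True, exist_ok=True)
    fields = [genome_id, ref_type, path]
    if species or assembly:
        fields += [species, assembly]
    with open(config_path, "a") as fh:
        fh.write("\t".join(fields) + "\n")
    return GenomeRef(genome_id, ref_type, path, species, assembly)


def lookup_genome(refs: Iterable[GenomeRef], genome_id: str, ref_type: str) -> str:
    """Exact-match lookup; failures are fatal *before* any job submission so
    a pipeline needing an index dies early with an actionable message."""
    refs = list(refs)
    by_id = [r for r in refs if r.genome_id == genome_id]
    if not by_id:
        known = sorted({r.genome_id for r in refs}, key=str.casefold)
        raise ConfigError(
            f"unknown genome ID {genome_id!r}; available IDs: {', '.join(known) or '(none)'}"
        )
    for ref in by_id:
        if ref.ref_type == ref_type:
            return ref.path
    have = sorted({r.ref_type for r in by_id})
    raise ConfigError(
        f"genome {genome_id!r} has no {ref_type!r} reference (available types: {', '.join(have)})"
    )


def list_genomes(refs: Iterable[GenomeRef]) -> list[tuple[str, str, str]]:
    """Deterministic table: sorted case-insensitively by ID then type,
    values reported verbatim."""
    return [
        (r.genome_id, r.ref_type, r.path)
        for r in sorted(refs, key=lambda r: (r.genome_id.casefold(), r.ref_type.casefold()))
    ]


def scan_for_references(directory: str | os.PathLike, ref_type: str) -> list[str]:
    """Minimal automatic reference search: scan a directory for filenames
    with extensions conventional for *ref_type*."""
    exts = {
        "fasta": (".fa", ".fasta", ".fa.gz", ".fasta.gz"),
        "gtf": (".gtf", ".gtf.gz"),
        "bowtie2": (".1.bt2",),
        "bowtie": (".1.ebwt",),
        "bwa": (".bwt",),
        "star": ("SAindex",),
        "hisat2": (".1.ht2",),
        "bismark": ("Bisulfite_Genome",),
    }.get(ref_type, ())
    hits = []
    directory = Path(directory)
    if not directory.is_dir():
        return []
    for entry in sorted(directory.iterdir()):
        if any(entry.name.endswith(ext) for ext in exts):
            hits.append(str(entry))
    return hits
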