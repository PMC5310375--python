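# flowlite: design and methods

## The execution model

A pipeline is a forest of module steps. Indentation is the only control
structure: a step one tab deeper than its predecessor runs after it
(series); steps at equal depth under the same parent are independent
branches. Two consecutive root-level steps are treated as parallel
branches — since deeper indentation is the series marker, equal depth is
read uniformly as "no ordering constraint". This is a documented dialect
choice; the practical consequence is that a root-level QC step never delays
a root-level trimming branch.

Each input group (one sample: a single FastQ, an R1/R2 pair, possibly
lane-merged) instantiates the whole tree once. Jobs therefore form a tree,
not a DAG: every non-root job has exactly one upstream. Convergent flows
(merge steps across samples) are deliberately out of scope; that
restriction is what keeps the syntax, the state files and the status
derivation simple. Depth is counted in tab characters only and leading
spaces are a syntax error, because silently mixed indentation produces
pipelines that look right and run wrong.

## Resource negotiation

Wrappers answer `--requirements` with `key: value` lines. Negotiation
rules, in units:

| request        | unit                 | rule                                             |
|----------------|----------------------|--------------------------------------------------|
| `cores: a-b`   | count                | grant = max(a, min(b, site max)); a > site max is fatal |
| `memory: 4G`   | bytes (K/M/G/T = 2^10..2^40; bare integer = bytes) | capped at site max |
| `time: 2h`     | minutes (`m/h/d`)    | × file count if `time_per_file: true`, then capped |

Site limits come from the layered config (defaults: 8 cores, 32G,
7 days). Defaults are deliberately generous for a mid-size cluster node;
sites tighten them in the site config. Memory suffixes are binary powers —
the convention schedulers themselves use for `--mem`.

Scheduler dialects are golden-tested strings: SLURM memory in MB
(`--mem=8192M`), GridEngine `h_vmem` per core with a G suffix, LSF `-M` in
MB. Dependency holds use success semantics (`afterok`, `done()`) so a
failed upstream cancels its descendants rather than letting them run on
missing inputs — matching the abort-and-report model of local mode.

## State: the `.run` file

All run state is one append-only text file per input group: a `/* ... */`
header (run id, creation time, resolved config, the planned jobs, the
pipeline tree) followed by TSV body lines. `start_000` is the sentinel job
owning the initial inputs. A step's outputs are body lines
`job_id<TAB>filename`; lifecycle markers `###CF_START/###CF_DONE/###CF_FAIL`
carry an ISO-8601 UTC timestamp as a third field. The timestamp on marker
lines is what lets `cf --qstat` report total duration as a pure function of
file contents — no clock is consulted except for runs with no events yet.

Status derivation: failed if a FAIL marker exists; done on a DONE marker
(or, for files written by other tooling, outputs with no START); running on
START without a terminal marker; skipped if any ancestor failed or was
skipped; queued otherwise. Appends are whole lines written under an
advisory `flock`, so parallel branches cannot interleave partial lines, and
any truncation prefix of a valid file still parses (fuzz-tested) — a killed
run never leaves the state unreadable.

Pass-through steps (QC tools that emit no `###CF_OUT`) are resolved
transitively: a job asking for its upstream's outputs walks up until it
finds a step that actually produced files, ending at `start_000`.

## Local mode

Local mode runs each group's jobs strictly in series (depth-first, parent
before children); groups run concurrently in a small thread pool
(`@max_parallel_groups`, default 2 — the threads only babysit
subprocesses). A nonzero exit marks the job failed and skips its
descendants; sibling branches and other groups continue. There is no
resource enforcement: grants are passed to wrappers but nothing polices
them, which is why local mode is recommended for testing and small runs
only. With `--background` the planned jobs are serialized to JSON and
replayed by a detached worker process, so the launching shell can exit; the
synchronous path is the default because it gives deterministic completion
for scripted use.

## Input helpers

Paired-end grouping tries read tokens in fixed precedence — `_R1/_R2`,
then `_1/_2`, then `.1/.2` — immediately before the extension stack
(`.fastq/.fq/.txt/.sra` ± `.gz`). First match wins per file; an orphan
read-2 is demoted to single-end with a warning. The token inventory and
precedence are a design choice (the modern Illumina `_R1` convention is the
least ambiguous, so it is tried first).

Encoding detection scans quality strings of up to `sample_reads` records
(default 1000): minimum ASCII < 59 means phred+33 (Sanger/Illumina 1.8+,
whose qualities start at `!` = 33, while legacy encodings never dip below
`;` = 59); minimum ≥ 64 means phred+64 (Illumina 1.3–1.5); the band in
between is reported `unknown` and the engine proceeds on a logged phred+33
assumption rather than guessing silently.

Lane-merge regexes (config key `@merge_regex`, repeatable) must have
exactly one capture group — the sample id; matching files are concatenated
(gzip streams concatenate legally) into `<capture>.fastq.gz` before
planning. The first pattern to match a file claims it. URLs (http/https/
ftp) become a `download` step prepended to that group's plan; the URL
basename joins pairing, so `x_1.fastq.gz`/`x_2.fastq.gz` URLs form a paired
group whose files exist only after the download job runs.

## Reporting

Run logs are wrapper stdout: `###CF*` markers among free tool chatter. The
parser never fails — unmarked lines are info events. Reports put errors
first in both the text and HTML renderings, before any step detail, so a
failed run is obvious from the first screenful; versions deduplicate per
tool (latest seen wins); commands are conserved exactly (wrapped, never
truncated, in the ≤100-column text rendering). The HTML document is
self-contained with inline styles. The submission log records PATH, user,
loaded environment modules, platform info and the fully resolved config —
including the notification address, since the log is a local file owned by
the submitting user. E-mail delivery is behind a sender interface whose
default writes `.email.txt`/`.email.html` beside the run file.

## Packaged wrappers and the stub toolbox

The 40 packaged modules cover QC (FastQC, FastQ Screen, MultiQC), trimming
(Trim Galore!, cutadapt, fastp), alignment (Bowtie 1/2, BWA aln/mem, STAR,
HISAT2, TopHat2, minimap2), bisulfite processing (Bismark align /
deduplicate / methylation extractor / report), quantification
(featureCounts, HTSeq, Salmon, kallisto, RSEM, StringTie), peak calling
(MACS2), BAM conversion/sorting/indexing/deduplication, coverage tracks,
SRA/URL downloads, subsampling and checksumming. Parameterization aims at
plausible defaults, not per-version flag fidelity. Command construction is
a pure function of (inputs, params, grants, genome paths), so every wrapper
is golden-testable with no tool installed; tool presence is checked only at
execution.

Output declaration is per wrapper: `none` (pass-through QC), `per_input`
(one output per file), `per_group` (one per sample), or `basename`
(downloads). While the wrapped tool runs, the wrapper exports the declared
output names in `CF_STUB_OUTPUTS`; real tools ignore it, and the stub
toolbox uses it to create the declared files. A stub answers version probes
with `<tool> 0.0.1-stub`, fails on a `--fail` flag, and writes a minimal
valid gzipped FastQ record into `.gz` outputs.

## What the synthetic data does and does not show

`make_synthetic_fastq` generates uniform random sequence with quality
characters drawn from the target encoding's legal band (phred+33: ASCII
33–58; phred+64: 64–104), deterministic per seed. It emulates file
structure — pairing, record format, gzip, encoding — not biology: no
adapter content, no quality profiles, no genome to align to. Passing tests
therefore demonstrate that the *engine* groups, plans, schedules, tracks
and reports correctly, and that wrappers construct the intended command
lines; they say nothing about the scientific output of the wrapped tools,
which is those tools' concern.

Test problem sizes (two paired samples × 3 steps end-to-end; 100 random
trees for ordering; 1,000 filename sets for pairing; 500 truncations for
fuzzing) were chosen to exercise every code path many times while keeping
the whole suite in seconds.

## Known limitations

No resume of partially completed pipelines, no DAG visualisation, no
convergent (multi-parent) steps, no job arrays or retry policies, no SMTP
delivery, no resource enforcement in local mode. Genome paths are stored
verbatim — whether a path is a file, directory or index prefix is the
consuming wrapper's business.
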