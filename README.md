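# flowlite

A lightweight, daemon-free workflow engine for next-generation sequencing
(NGS) pipelines, in the spirit of Cluster Flow.

Most NGS analyses — QC, adapter trimming, alignment, quantification — are
near-linear chains of standard tools applied per sample. Full workflow
systems (Snakemake, Nextflow) buy their generality with complexity:
pipeline code has to be written before anything runs. `flowlite` targets
the other end of the trade-off: it ships 40 ready-made tool-wrapper
modules and ready-to-run pipelines, uses a deliberately restricted data
flow (a tree per sample, no convergence), and keeps all run state in plain
append-only text files, so there is nothing to install beyond the package
and nothing running in the background to monitor jobs.

It is aimed at small-to-medium groups who want `cf fastq_bowtie2 *.fastq.gz`
to just work on a shared cluster or a laptop.

## How it works

* **Pipelines** are tab-indented text: `#module [params…]` lines, where a
  line indented one tab deeper runs *after* (in series with) the nearest
  shallower line, and lines at equal depth are independent parallel
  branches. `@key value` lines before the first step are directives
  (e.g. a required reference type).
* **Modules** are standalone wrapper executables. At launch the engine asks
  each one for resources (`--requirements`); requests like `cores: 1-8`,
  `memory: 4G`, `time: 2h` per file are clamped to the site limits
  (grant = min(request max, cluster max), never below the request min;
  per-file time × file count, capped). At run time a module builds and
  executes the tool command and reports through greppable
  `###CF_OUT/###CF_VERS/###CFCMD/###CF_ERR` marker lines.
* **Scheduling**: each input group's step tree becomes a chain of jobs
  submitted with the scheduler's native dependency holds —
  `sbatch --dependency=afterok:<id>` (SLURM), `qsub -hold_jid <id>`
  (GridEngine), `bsub -w "done(<id>)"` (LSF) — or run serially in local
  mode. `--dry_run` prints every submission command and touches nothing.
* **State**: one `.run` file per input group records the plan, the initial
  inputs under the `start_000` sentinel, and every step's outputs and
  lifecycle markers, append-only. `cf --qstat` derives queued / running /
  done / failed / skipped purely from these files.
* **Helpers**: paired-end FastQ files are grouped automatically
  (`_R1/_R2`, `_1/_2`, `.1/.2`), quality encoding (phred+33 vs phred+64)
  is detected from the quality bytes, configured regexes merge lane-split
  samples, and URLs are accepted as inputs via a prepended download step.
* **Reports**: when a local run finishes, the logs are parsed into text and
  self-contained HTML completion reports — errors first, then commands,
  per-step durations and a software-version table — written next to the
  run files (the default "e-mail" is a file; real delivery is pluggable).

## Worked example

Entirely synthetic — two paired-end samples and stub tools:

```bash
python -c "
from flowlite.wrappers.stubs import make_stub_toolbox, make_synthetic_fastq
make_stub_toolbox('stubs')
for i, s in enumerate(['liver', 'kidney']):
    make_synthetic_fastq('fastq', sample=s, n_reads=100, paired=True, seed=i)
"
export PATH=$PWD/stubs:$PATH

cf --local fastq_preprocess fastq/*.fastq.gz
```

prints

```
Pipeline fastq_preprocess: 2 input group(s), 6 job(s) (3 per group)
ok       cf_fastq_preprocess_20260927-201745_fastp_0
ok       cf_fastq_preprocess_20260927-201745_fastp_1
ok       cf_fastq_preprocess_20260927-201745_subsample_0
ok       cf_fastq_preprocess_20260927-201745_subsample_1
ok       cf_fastq_preprocess_20260927-201745_trim_galore_0
ok       cf_fastq_preprocess_20260927-201745_trim_galore_1
```

The four FastQ files were recognised as two paired samples; the 3-step
pipeline (trim → quality-filter → subsample) was instantiated once per
sample (6 jobs) and run serially per sample. `cf --qstat` then shows,
derived only from the `.run` files:

```
== fastq_preprocess_20260927-201745_0 (fastq_preprocess)
   dir: .
   duration: 1s   steps remaining: 0
   done     trim_galore (cf_fastq_preprocess_20260927-201745_trim_galore_0)
   done     fastp (cf_fastq_preprocess_20260927-201745_fastp_0)
   done     subsample (cf_fastq_preprocess_20260927-201745_subsample_0)
...
```

and each sample has a `*_report.txt` / `*_report.html` beginning

```
Cluster Flow run report: fastq_preprocess_20260927-201745_0
Pipeline completed successfully
```

followed by the executed commands and a tool-version table. Add
`--dry_run`, or set `@cluster_environment slurm` in the config, to see the
scheduler submissions instead of running anything.

## Layout

```
src/flowlite/
  config.py      layered @key-value config + genome reference table
  pipeline.py    pipeline syntax -> step tree -> per-group job plan
  module_api.py  wrapper protocol: negotiation, invocation, markers
  scheduler.py   SLURM/GridEngine/LSF dialects, local serial executor
  runfile.py     append-only .run state files and status derivation
  helpers.py     pairing, encoding detection, lane merging, URL inputs
  reporting.py   log parsing, text/HTML reports, submission log
  wrappers/      40 packaged module specs, runtime, stub toolbox
  modules/       the packaged wrapper executables
  pipelines/     packaged pipeline definitions
  cli.py         the cf entry point
```
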