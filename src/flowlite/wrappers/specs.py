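"""Declarative definitions of the packaged tool-wrapper modules.

Each :class:`WrapperSpec` describes one module: the tool it wraps, the
resources it asks for at negotiation time, which reference types it needs,
and command templates for single-end and paired-end input groups.  Command
construction is a pure function of (inputs, params, granted resources,
genome paths) — no tool needs to be installed to generate or golden-test a
command, and tool presence is only checked at execution time.

Template placeholders::

    {tool}     executable name          {cores}   granted cores
    {mem_mb}   granted memory in MB     {genome}  resolved reference path
    {inputs}   all input files          {input}   first input file
    {input1} {input2}  paired reads     {output}  first declared output
    {group}    derived sample name

Output declaration (``out_mode``): ``none`` (QC-style pass-through —
downstream steps inherit this step's inputs), ``per_input`` (one output per
input file, ``<stem><out_suffix>``), ``per_group`` (one output per group,
``<group><out_suffix>``), ``basename`` (the input's URL/path basename —
download modules).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class WrapperSpec:
    name: str
    category: str  # QC | trimming | alignment | quantification | methylation |
    #                peak_calling | conversion | coverage | download | misc
    tool: str  # executable the module wraps
    single: str  # command template for single-end groups ("" = unsupported)
    paired: str = ""  # command template for paired groups ("" = unsupported)
    cores: str = "1"  # requested cores, "n" or "lo-hi"
    memory: str = "2G"
    time: str = "2h"
    time_per_file: bool = False
    required_ref_types: tuple[str, ...] = ()
    environment_modules: tuple[str, ...] = ()
    out_mode: str = "none"  # none | per_input | per_group | basename
    out_suffix: str = ""
    version_args: tuple[str, ...] = ("--version",)


def _w(**kw) -> WrapperSpec:
    kw.setdefault("environment_modules", (kw["tool"],))
    return WrapperSpec(**kw)


PACKAGED: tuple[WrapperSpec, ...] = (
    # --- QC -----------------------------------------------------------------
    _w(name="fastqc", category="QC", tool="fastqc",
       single="{tool} -t {cores} {inputs}", paired="{tool} -t {cores} {inputs}",
       cores="1-4", memory="4G", time="1h", time_per_file=True),
    _w(name="fastq_screen", category="QC", tool="fastq_screen",
       single="{tool} --threads {cores} {inputs}", paired="{tool} --threads {cores} {inputs}",
       cores="1-8", memory="8G", time="2h", time_per_file=True),
    _w(name="multiqc", category="QC", tool="multiqc",
       single="{tool} .", paired="{tool} .", cores="1", memory="2G", time="30m"),
    # --- trimming -----------------------------------------------------------
    _w(name="trim_galore", category="trimming", tool="trim_galore",
       single="{tool} --cores {cores} {inputs}",
       paired="{tool} --cores {cores} --paired {input1} {input2}",
       cores="1-4", memory="4G", time="3h", time_per_file=True,
       out_mode="per_input", out_suffix="_trimmed.fq.gz"),
    _w(name="cutadapt", category="trimming", tool="cutadapt",
       single="{tool} -j {cores} -o {output} {input}",
       paired="{tool} -j {cores} {input1} {input2}",
       cores="1-4", memory="4G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".trimmed.fastq.gz"),
    _w(name="fastp", category="trimming", tool="fastp",
       single="{tool} -w {cores} -i {input}",
       paired="{tool} -w {cores} -i {input1} -I {input2}",
       cores="1-8", memory="4G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".fastp.fastq.gz"),
    # --- alignment ----------------------------------------------------------
    _w(name="bowtie", category="alignment", tool="bowtie",
       single="{tool} -p {cores} {genome} {input}",
       paired="{tool} -p {cores} {genome} -1 {input1} -2 {input2}",
       cores="1-8", memory="8G", time="4h", time_per_file=True,
       required_ref_types=("bowtie",), out_mode="per_group", out_suffix="_bowtie.bam"),
    _w(name="bowtie2", category="alignment", tool="bowtie2",
       single="{tool} -p {cores} -x {genome} -U {input}",
       paired="{tool} -p {cores} -x {genome} -1 {input1} -2 {input2}",
       cores="1-8", memory="8G", time="4h", time_per_file=True,
       required_ref_types=("bowtie2",), out_mode="per_group", out_suffix="_bt2.bam"),
    _w(name="bwa_aln", category="alignment", tool="bwa",
       single="{tool} aln -t {cores} {genome} {input}",
       cores="1-8", memory="8G", time="4h", time_per_file=True,
       required_ref_types=("bwa",), out_mode="per_group", out_suffix="_bwa.bam",
       version_args=()),
    _w(name="bwa_mem", category="alignment", tool="bwa",
       single="{tool} mem -t {cores} {genome} {input}",
       paired="{tool} mem -t {cores} {genome} {input1} {input2}",
       cores="1-16", memory="16G", time="4h", time_per_file=True,
       required_ref_types=("bwa",), out_mode="per_group", out_suffix="_bwamem.bam",
       version_args=()),
    _w(name="star", category="alignment", tool="STAR",
       single="{tool} --runThreadN {cores} --genomeDir {genome} --readFilesIn {input}",
       paired="{tool} --runThreadN {cores} --genomeDir {genome} --readFilesIn {input1} {input2}",
       cores="4-16", memory="32G", time="4h", time_per_file=True,
       required_ref_types=("star",), out_mode="per_group",
       out_suffix="_Aligned.out.bam", version_args=("--version",)),
    _w(name="hisat2", category="alignment", tool="hisat2",
       single="{tool} -p {cores} -x {genome} -U {input}",
       paired="{tool} -p {cores} -x {genome} -1 {input1} -2 {input2}",
       cores="1-8", memory="8G", time="4h", time_per_file=True,
       required_ref_types=("hisat2",), out_mode="per_group", out_suffix="_hisat2.bam"),
    _w(name="tophat", category="alignment", tool="tophat2",
       single="{tool} -p {cores} {genome} {input}",
       paired="{tool} -p {cores} {genome} {input1} {input2}",
       cores="1-8", memory="16G", time="8h", time_per_file=True,
       required_ref_types=("bowtie2", "gtf"), out_mode="per_group",
       out_suffix="_tophat.bam"),
    _w(name="minimap2", category="alignment", tool="minimap2",
       single="{tool} -t {cores} -a {genome} {input}",
       paired="{tool} -t {cores} -a {genome} {input1} {input2}",
       cores="1-8", memory="16G", time="4h", time_per_file=True,
       required_ref_types=("fasta",), out_mode="per_group", out_suffix="_mm2.bam"),
    # --- methylation --------------------------------------------------------
    _w(name="bismark_align", category="methylation", tool="bismark",
       single="{tool} -p {cores} --genome {genome} {input}",
       paired="{tool} -p {cores} --genome {genome} -1 {input1} -2 {input2}",
       cores="2-8", memory="16G", time="8h", time_per_file=True,
       required_ref_types=("bismark",), out_mode="per_group",
       out_suffix="_bismark.bam"),
    _w(name="bismark_deduplicate", category="methylation", tool="deduplicate_bismark",
       single="{tool} {input}", paired="{tool} -p {input}",
       cores="1", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".deduplicated.bam"),
    _w(name="bismark_methxtract", category="methylation",
       tool="bismark_methylation_extractor",
       single="{tool} --multicore {cores} {input}",
       paired="{tool} --multicore {cores} -p {input}",
       cores="1-4", memory="8G", time="4h", time_per_file=True,
       out_mode="per_input", out_suffix=".bedGraph.gz"),
    _w(name="bismark_report", category="methylation", tool="bismark2report",
       single="{tool}", paired="{tool}", cores="1", memory="2G", time="30m"),
    # --- quantification -----------------------------------------------------
    _w(name="featurecounts", category="quantification", tool="featureCounts",
       single="{tool} -T {cores} -a {genome} -o {output} {inputs}",
       paired="{tool} -T {cores} -p -a {genome} -o {output} {inputs}",
       cores="1-8", memory="8G", time="2h", time_per_file=True,
       required_ref_types=("gtf",), out_mode="per_group", out_suffix="_counts.txt",
       version_args=("-v",)),
    _w(name="htseq_count", category="quantification", tool="htseq-count",
       single="{tool} {input} {genome}", paired="{tool} -r pos {input} {genome}",
       cores="1", memory="8G", time="4h", time_per_file=True,
       required_ref_types=("gtf",), out_mode="per_group", out_suffix="_htseq.txt"),
    _w(name="salmon", category="quantification", tool="salmon",
       single="{tool} quant -p {cores} -i {genome} -r {input} -o {group}_salmon",
       paired="{tool} quant -p {cores} -i {genome} -1 {input1} -2 {input2} -o {group}_salmon",
       cores="1-8", memory="16G", time="2h", time_per_file=True,
       required_ref_types=("salmon",), out_mode="per_group", out_suffix="_quant.sf"),
    _w(name="kallisto", category="quantification", tool="kallisto",
       single="{tool} quant -t {cores} -i {genome} --single {input} -o {group}_kallisto",
       paired="{tool} quant -t {cores} -i {genome} {input1} {input2} -o {group}_kallisto",
       cores="1-8", memory="8G", time="2h", time_per_file=True,
       required_ref_types=("kallisto",), out_mode="per_group",
       out_suffix="_abundance.tsv", version_args=("version",)),
    _w(name="rsem", category="quantification", tool="rsem-calculate-expression",
       single="{tool} -p {cores} {input} {genome} {group}",
       paired="{tool} -p {cores} --paired-end {input1} {input2} {genome} {group}",
       cores="1-8", memory="16G", time="4h", time_per_file=True,
       required_ref_types=("rsem",), out_mode="per_group", out_suffix=".genes.results"),
    _w(name="stringtie", category="quantification", tool="stringtie",
       single="{tool} -p {cores} -G {genome} {input}",
       paired="{tool} -p {cores} -G {genome} {input}",
       cores="1-8", memory="8G", time="2h", time_per_file=True,
       required_ref_types=("gtf",), out_mode="per_group", out_suffix="_stringtie.gtf"),
    # --- peak calling -------------------------------------------------------
    _w(name="macs2", category="peak_calling", tool="macs2",
       single="{tool} callpeak -t {input} -n {group}",
       paired="{tool} callpeak -f BAMPE -t {input} -n {group}",
       cores="1", memory="8G", time="4h",
       out_mode="per_group", out_suffix="_peaks.narrowPeak"),
    # --- conversion / sorting / indexing ------------------------------------
    _w(name="sam_to_bam", category="conversion", tool="samtools",
       single="{tool} view -@ {cores} -bS {input}",
       paired="{tool} view -@ {cores} -bS {input}",
       cores="1-4", memory="4G", time="1h", time_per_file=True,
       out_mode="per_input", out_suffix=".bam"),
    _w(name="samtools_sort", category="conversion", tool="samtools",
       single="{tool} sort -@ {cores} -o {output} {input}",
       paired="{tool} sort -@ {cores} -o {output} {input}",
       cores="1-4", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".sorted.bam"),
    _w(name="samtools_index", category="conversion", tool="samtools",
       single="{tool} index {input}", paired="{tool} index {input}",
       cores="1", memory="2G", time="30m", time_per_file=True),
    _w(name="samtools_sort_index", category="conversion", tool="samtools",
       single="{tool} sort -@ {cores} -o {output} {input}",
       paired="{tool} sort -@ {cores} -o {output} {input}",
       cores="1-4", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".sorted.bam"),
    _w(name="samtools_flagstat", category="conversion", tool="samtools",
       single="{tool} flagstat {input}", paired="{tool} flagstat {input}",
       cores="1", memory="2G", time="30m", time_per_file=True),
    _w(name="samtools_dedup", category="conversion", tool="samtools",
       single="{tool} markdup -r {input} {output}",
       paired="{tool} markdup -r {input} {output}",
       cores="1-4", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".markdup.bam"),
    _w(name="picard_markduplicates", category="conversion", tool="picard",
       single="{tool} MarkDuplicates I={input} O={output}",
       paired="{tool} MarkDuplicates I={input} O={output}",
       cores="1", memory="16G", time="4h", time_per_file=True,
       out_mode="per_input", out_suffix=".dedup.bam"),
    _w(name="bam_to_fastq", category="conversion", tool="samtools",
       single="{tool} fastq {input}", paired="{tool} fastq {input}",
       cores="1-4", memory="4G", time="1h", time_per_file=True,
       out_mode="per_input", out_suffix=".fastq.gz"),
    # --- coverage -----------------------------------------------------------
    _w(name="bedtools_genomecov", category="coverage", tool="bedtools",
       single="{tool} genomecov -bg -ibam {input}",
       paired="{tool} genomecov -bg -ibam {input}",
       cores="1", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".bedGraph"),
    _w(name="deeptools_bamcoverage", category="coverage", tool="bamCoverage",
       single="{tool} -p {cores} -b {input} -o {output}",
       paired="{tool} -p {cores} -b {input} -o {output}",
       cores="1-8", memory="8G", time="2h", time_per_file=True,
       out_mode="per_input", out_suffix=".bw"),
    # --- download -----------------------------------------------------------
    _w(name="sra_fetch", category="download", tool="prefetch",
       single="{tool} -o {output} {input}", paired="{tool} -o {output} {input}",
       cores="1", memory="2G", time="4h", time_per_file=True,
       out_mode="per_input", out_suffix=".sra"),
    _w(name="sra_fqdump", category="download", tool="fastq-dump",
       single="{tool} --gzip {input}", paired="{tool} --gzip --split-files {input}",
       cores="1", memory="4G", time="4h", time_per_file=True,
       out_mode="per_input", out_suffix=".fastq.gz"),
    _w(name="download", category="download", tool="curl",
       single="{tool} -fsSL -o {output} {input}",
       paired="{tool} -fsSL -o {output} {input}",
       cores="1", memory="1G", time="4h", time_per_file=True,
       out_mode="basename"),
    # --- misc ---------------------------------------------------------------
    _w(name="subsample", category="misc", tool="seqtk",
       single="{tool} sample {input} 1000", paired="{tool} sample {input} 1000",
       cores="1", memory="2G", time="1h", time_per_file=True,
       out_mode="per_input", out_suffix=".sub.fastq.gz", version_args=()),
    _w(name="md5checksum", category="misc", tool="md5sum",
       single="{tool} {inputs}", paired="{tool} {inputs}",
       cores="1", memory="1G", time="30m", time_per_file=True),
)

BY_NAME: dict[str, WrapperSpec] = {s.name: s for s in PACKAGED}

assert len(BY_NAME) == len(PACKAGED), "duplicate wrapper names in roster"
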