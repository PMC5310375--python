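@require_genome bowtie2
#fastqc
#trim_galore
	#bowtie2
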