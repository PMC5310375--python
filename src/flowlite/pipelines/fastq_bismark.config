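@require_genome bismark
#fastqc
#trim_galore
	#bismark_align
		#bismark_deduplicate
			#bismark_methxtract
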