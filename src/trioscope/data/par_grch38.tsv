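# GRCh38 pseudoautosomal regions (1-based inclusive coordinates on chrX).
# Sites inside these intervals segregate autosomally and are classified with diploid rules.
chrom	start	end	name
X	10001	2781479	PAR1
X	155701383	156030895	PAR2
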