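# Digitized reference-cohort CNV table: ten de novo heterozygous micro-CNVs in eight probands.
# Coordinates are GRCh38. printed_size is stored verbatim; one value is printed with a sign typo
# ("-4198") although its coordinates give 4198. All ten computed lengths equal end - start.
# The source table prints 8 subject columns over 10 CNV columns; the assignment of the doubled
# columns (subject 74 -> PCDH15+TRPM3, subject 98 -> PDSS1+SLCO1B1, PLEKHM1 -> subject 75) is
# inferred from column order.
subject_id	sex	chrom	start	end	cnv_type	printed_size	cytoband	genes	location	inheritance
19	M	chr16	6864585	6865758	DEL	1173	16p13.3	RBFOX1	intron 3	de_novo
25	F	chr3	192671334	192672351	DEL	1017	3q29	FGF12	intron 2	de_novo
52	F	chr19	4559368	4562532	DEL	3164	19p13.3	SEMA6B	exon 1 and intron 1	de_novo
54	F	chr3	133414146	133418344	DEL	-4198	3q22.1	BFSP2	intron 1	de_novo
74	M	chr10	54921983	54925066	DEL	3083	10q21.1	PCDH15	intron 3	de_novo
74	M	chr9	71289426	71290609	DUP	1183	9q21.12	TRPM3	intron 1	de_novo
75	M	chr17	45440911	45508556	DEL	67645	17q21.31	PLEKHM1	exon 6 (LRRC37A4P); exon 1-intron 9 (PLEKHM1)	de_novo
89	F	chr2	1521403	1522564	DEL	1161	2p25.3	TPO	intron 15	de_novo
98	F	chr10	26709200	26711140	DEL	1940	10p12.1	PDSS1	intron 4, exon 5, intron 5	de_novo
98	F	chr12	21165423	21166430	DEL	1007	12p12.1	SLCO1B1	intron 2	de_novo
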