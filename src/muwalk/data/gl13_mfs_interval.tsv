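chrom	start	end	read_count	target_gene	insertion_site	deg
chr3	4952465	4952473	23	Non-genic insertion	-	-
chr3	10281062	10281070	727	GRMZM2G118243	Exon 21	Yes
chr3	14929161	14929169	402	GRMZM2G088443	Exon 1	No
chr3	14929196	14929204	36	GRMZM2G088443	Exon 1	No
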