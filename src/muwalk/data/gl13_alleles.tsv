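id	allele	progenitor	mutagen	chrom	pos	mutation	ref_b73	a632	mo17	lesion	category	aa_position	aa_ref	aa_alt	distance_bp
1	gl13-94-1001-746	A632	EMS	chr3	10282947	del:AC	AC	AC	AC	2 bp deletion in 47 bp downstream of stop codon	downstream	-	-	-	47
2	gl13-94-1001-1481	A632	EMS	chr3	10273165	G->A	G	G	G	28 bp upstream of start codon	upstream	-	-	-	28
3	gl13-2:15-33	Mo17	EMS	chr3	10282710	G->A	G	G	G	Non-synonymous	non_synonymous	1369	G	S	-
4	gl13-2:207-44	Mo17	EMS	chr3	10277900	G->A	G	G	G	PTC	PTC	529	-	*	-
5	gl13-2:225-43	Mo17	EMS	chr3	10278657	C->T	C	C	C	PTC	PTC	655	Q	*	-
6	gl13-N211B	ND	EMS	chr3	10276510	C->T	C	C	C	PTC	PTC	374	Q	*	-
7	gl13-N1478B	ND	EMS	chr3	10279970	C->T	C	C	C	PTC	PTC	985	Q	*	-
8	gl13-Nec8495	ND	ND	chr3	10282712	C->A	C	C	C	synonymous	synonymous	-	-	-	-
9	gl13-U440B	ND	ND	chr3	10282712	C->A	C	C	C	synonymous	synonymous	-	-	-	-
10	gl13-N169	ND	EMS	chr3	10281826	G->A	G	G	G	Non-synonymous	non_synonymous	1335	G	R	-
11	gl13-Mu90-3134B1	Q60	Mu	chr3	10281062	Mu1	-	-	-	Mu insertion (Mu1)	exon_insertion	-	-	-	-
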