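# Mitochondrial genome annotation of Epitrimerus sabinae (GenBank KR604966)
# provenance: table-transcription; genome length 13531 bp (circular)
# rows kept in printed order: trnK and CR are printed out of coordinate order
# printed_gap = intergenic nucleotides to the coordinate-predecessor as printed (negative = overlap)
gene	class	strand	start	end	anticodon	printed_gap	start_codon	stop_codon
cox1	PCG	J	1	1533	.	14	ATT	TAA
cox2	PCG	J	1533	2198	.	-1	ATG	TAA
trnK	tRNA	J	2411	2471	TTT	-10	.	.
trnD	tRNA	J	2201	2254	GTC	2	.	.
atp8	PCG	J	2256	2420	.	1	ATT	TAA
atp6	PCG	J	2566	3207	.	0	ATG	TAA
cox3	PCG	J	3207	3998	.	-1	ATG	TAG
trnG	tRNA	J	3987	4044	TCC	-12	.	.
nad3	PCG	J	4043	4381	.	-2	ATG	TAA
trnA	tRNA	J	4381	4433	TGC	-1	.	.
trnR	tRNA	J	4425	4476	TCG	-9	.	.
trnN	tRNA	J	4466	4518	GTT	-11	.	.
trnS1	tRNA	J	4514	4568	TCT	-5	.	.
trnI	tRNA	J	4564	4612	GAT	-5	.	.
trnE	tRNA	J	4613	4665	TTC	0	.	.
trnF	tRNA	N	4663	4716	GAA	-3	.	.
nad5	PCG	N	4716	6303	.	-1	ATT	T
trnH	tRNA	N	6313	6366	GTG	9	.	.
nad4	PCG	N	6383	7621	.	16	ATG	TAA
nad4L	PCG	N	7621	7878	.	-1	ATC	TAA
trnP	tRNA	N	7888	7941	TGG	9	.	.
nad6	PCG	J	7942	8385	.	0	ATG	TAA
trnT	tRNA	J	8366	8421	TGT	-20	.	.
cob	PCG	J	8423	9515	.	1	ATA	T
trnS2	tRNA	J	9516	9565	TGA	0	.	.
nad1	PCG	N	9566	10442	.	0	ATA	T
trnL2	tRNA	N	10449	10511	TAA	6	.	.
trnL1	tRNA	N	10509	10567	TAG	-3	.	.
trnY	tRNA	J	10570	10616	GTA	2	.	.
trnQ	tRNA	J	10624	10676	TTG	7	.	.
rrnS	rRNA	J	10677	11342	.	0	.	.
trnV	tRNA	J	11343	11396	TAC	0	.	.
rrnL	rRNA	J	11397	12401	.	0	.	.
CR	CR	.	2472	2565	.	0	.	.
trnW	tRNA	J	12402	12468	TCA	0	.	.
nad2	PCG	J	12470	13400	.	1	ATA	T
trnM	tRNA	J	13401	13462	CAT	0	.	.
trnC	tRNA	N	13464	13517	GCA	1	.	.
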