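# Mitochondrial genome annotation of Phyllocoptes taishanensis (GenBank KR604967)
# provenance: table-transcription; genome length 13475 bp (circular)
# printed_gap = intergenic nucleotides to the coordinate-predecessor as printed (negative = overlap)
gene	class	strand	start	end	anticodon	printed_gap	start_codon	stop_codon
cox1	PCG	J	1	1554	.	10	CTG	TAA
cox2	PCG	J	1555	2220	.	0	ATG	TAG
trnK	tRNA	J	2221	2280	TTT	0	.	.
trnD	tRNA	J	2279	2332	GTC	-2	.	.
atp8	PCG	J	2333	2485	.	0	CTG	TAA
atp6	PCG	J	2485	3129	.	-1	ATG	TAA
cox3	PCG	J	3129	3914	.	-1	ATG	TAA
trnG	tRNA	J	3909	3966	TCC	-6	.	.
nad3	PCG	J	3966	4299	.	-1	ATC	T
trnA	tRNA	J	4300	4346	TGC	0	.	.
trnR	tRNA	J	4343	4393	TCG	-4	.	.
trnN	tRNA	J	4383	4436	GTT	-11	.	.
trnS1	tRNA	J	4430	4483	TCT	-7	.	.
trnI	tRNA	J	4479	4528	GAT	-5	.	.
trnE	tRNA	J	4529	4582	TTC	0	.	.
trnF	tRNA	N	4581	4632	GAA	-2	.	.
nad5	PCG	N	4633	6222	.	0	ATT	TAA
trnH	tRNA	N	6235	6289	GTG	12	.	.
nad4	PCG	N	6291	7526	.	1	ATG	TAA
nad4L	PCG	N	7526	7789	.	-1	ATT	TAA
trnP	tRNA	N	7799	7852	TGG	9	.	.
nad6	PCG	J	7852	8287	.	-1	ATG	T
trnT	tRNA	J	8287	8341	TGT	-1	.	.
cob	PCG	J	8346	9437	.	4	ATC	TAA
trnS2	tRNA	J	9437	9484	TGA	-1	.	.
nad1	PCG	N	9486	10370	.	1	ATA	TAG
trnL2	tRNA	N	10371	10429	TAA	0	.	.
trnL1	tRNA	N	10431	10489	TAG	1	.	.
trnY	tRNA	J	10490	10536	GTA	0	.	.
trnQ	tRNA	J	10539	10591	TTG	2	.	.
rrnS	rRNA	J	10592	11255	.	0	.	.
trnV	tRNA	J	11256	11306	TAC	0	.	.
rrnL	rRNA	J	11307	12310	.	0	.	.
CR	CR	.	12311	12357	.	0	.	.
trnW	tRNA	J	12358	12412	TCA	0	.	.
nad2	PCG	J	12413	13352	.	0	ATT	T
trnM	tRNA	J	13353	13413	CAT	0	.	.
trnC	tRNA	N	13413	13465	GCA	-1	.	.
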