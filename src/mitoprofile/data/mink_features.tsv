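# Gene layout template for the Mustela lutreola reference mitogenome (16,504 bp).
# Columns: name	kind	start	end	strand	anticodon
# Coordinates are 1-based inclusive on the H-strand. kind is one of
# PCG, tRNA, rRNA, origin, control_region, other. "." means not applicable.
tRNA-Phe	tRNA	1	69	H	GAA
rrnS	rRNA	70	1028	H	.
tRNA-Val	tRNA	1029	1096	H	TAC
rrnL	rRNA	1095	2665	H	.
tRNA-Leu(UUA)	tRNA	2666	2740	H	TAA
nad1	PCG	2743	3698	H	.
tRNA-Ile	tRNA	3699	3767	H	GAT
tRNA-Gln	tRNA	3765	3838	L	TTG
tRNA-Met	tRNA	3840	3908	H	CAT
nad2	PCG	3909	4950	H	.
tRNA-Trp	tRNA	4951	5017	H	TCA
tRNA-Ala	tRNA	5028	5096	L	TGC
tRNA-Asn	tRNA	5098	5170	L	GTT
OL	origin	5171	5205	L	.
tRNA-Cys	tRNA	5203	5269	L	GCA
tRNA-Tyr	tRNA	5271	5338	L	GTA
cox1	PCG	5340	6884	H	.
tRNA-Ser(UCA)	tRNA	6882	6950	L	TGA
tRNA-Asp	tRNA	6956	7022	H	GTC
cox2	PCG	7023	7706	H	.
tRNA-Lys	tRNA	7710	7776	H	TTT
atp8	PCG	7778	7981	H	.
atp6	PCG	7939	8619	H	.
cox3	PCG	8619	9402	H	.
tRNA-Gly	tRNA	9403	9471	H	TCC
nad3	PCG	9472	9818	H	.
tRNA-Arg	tRNA	9819	9886	H	TCG
nad4l	PCG	9887	10183	H	.
nad4	PCG	10177	11554	H	.
tRNA-His	tRNA	11555	11623	H	GTG
tRNA-Ser(AGC)	tRNA	11624	11685	H	GCT
tRNA-Leu(CUA)	tRNA	11686	11755	H	TAG
nad5	PCG	11756	13576	H	.
nad6	PCG	13560	14090	L	.
tRNA-Glu	tRNA	14094	14162	L	TTC
cytb	PCG	14167	15306	H	.
tRNA-Thr	tRNA	15307	15374	H	TGT
tRNA-Pro	tRNA	15374	15439	L	TGG
CR	control_region	15440	16504	H	.
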