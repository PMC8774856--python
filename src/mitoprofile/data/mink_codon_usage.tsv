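# Pooled codon usage of the 13 protein-coding genes of the Mustela lutreola
# reference mitogenome, as percentages of all codons (incomplete termination
# codons completed by polyadenylation before counting). Vertebrate
# mitochondrial code; "*" marks termination codons.
# Columns: codon	amino_acid	percent
TTT	F	2.65
TTC	F	3.44
TTA	L	3.31
TTG	L	0.58
CTT	L	1.89
CTC	L	1.92
CTA	L	7.20
CTG	L	1.10
ATT	I	3.99
ATC	I	4.65
ATA	M	5.28
ATG	M	1.18
GTT	V	0.84
GTC	V	1.10
GTA	V	2.42
GTG	V	0.39
TCT	S	1.42
TCC	S	1.79
TCA	S	2.63
TCG	S	0.13
AGT	S	0.47
AGC	S	1.05
CCT	P	1.16
CCC	P	1.76
CCA	P	2.05
CCG	P	0.13
ACT	T	2.08
ACC	T	2.15
ACA	T	3.73
ACG	T	0.42
GCT	A	1.47
GCC	A	2.68
GCA	A	2.39
GCG	A	0.18
TAT	Y	1.39
TAC	Y	2.08
TAA	*	0.32
TAG	*	0.00
AGA	*	0.03
AGG	*	0.00
CAT	H	0.60
CAC	H	1.92
CAA	Q	2.10
CAG	Q	0.21
AAT	N	1.52
AAC	N	2.44
AAA	K	2.44
AAG	K	0.21
GAT	D	0.58
GAC	D	1.18
GAA	E	2.08
GAG	E	0.47
TGT	C	0.29
TGC	C	0.39
TGA	W	2.29
TGG	W	0.47
CGT	R	0.16
CGC	R	0.42
CGA	R	1.00
CGG	R	0.11
GGT	G	0.79
GGC	G	1.26
GGA	G	2.68
GGG	G	0.92
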