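# Synthetic default motif library for control-region annotation.
# The conserved-element consensus sequences of mustelid control regions are not
# bundled verbatim (they are not reproducible from any single printed source);
# the motifs below are synthetic stand-ins with the documented functional cores
# (the GCCCCAT D-loop termination motif, the ATGN9CAT palindromic core inside
# ETAS1 and CSB1, the TATAT termination-associated core in TAS-A, a C-rich
# CSB2). Users annotating real genomes should supply a species-appropriate
# library with the same schema.
# Columns: element	domain	motif	max_edits
ETAS1	ETAS	ATGTATTAACTGCATACCTA	3
dloop_termination	ETAS	GCCCCAT	1
TAS-A	ETAS	CACCTATATGTATATCGTGC	3
F_box	CD	GTACATAGCACATTCAAG	3
E_box	CD	CCTAGAGGTTCAAATCAGAC	3
D_box	CD	TGGACTAATGACTAATCAGC	3
C_box	CD	CCTCCGTGAAACCAGCAACC	3
B_box	CD	GACATCTGGTTCTTACTTCA	3
CSB1	CSB	ATGAATAACCCCCATGGTCT	3
CSB2	CSB	AAACCCCCCCTCCCCC	2
CSB3	CSB	CAAACCCCGACAGCTACTC	3
HSP	CSB	AGGGTCATAAAGCCTA	2
LSP	CSB	TTAACAGTCACACCCC	2
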