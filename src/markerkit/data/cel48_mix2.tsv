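id	sequence	orientation	length	v_ul	n_degenerate
F1	TCTTGAGTGAAGCTCCAGACTA	forward	22	1	0
F2	TGCTTAGCGA[AG]GCGCCCAA	forward	19	2	1
F3	GAGCGA[AG]GC[I]CC[I]GATTAC	forward	19	2	1
F4	TGAGCGAGGCTCC[GT]GAC[CT]A	forward	19	4	2
F5	TGATATGCGAAGCACCTGA[CT]TATG	forward	24	2	1
F6	TCATATG[CT]GAAGC[GA]CC[TG]GATTAC	forward	23	8	3
F7	TGATATGCGAGGCACCGGATTA	forward	22	1	0
F8	TGAACTGTGAAGCTCCTGATCAA	forward	23	1	0
F9	TGTGTGTTGAAGCGCCTGATTAC	forward	23	1	0
F10	TGATTGT[I]GAAGCTCC[TG]GA[CT]TATG	forward	24	4	2
F11	ATCGTCGAAGCGCCTGACCA	forward	20	1	0
F12	ATCGACGAGGCGCCCGA	forward	17	1	0
F13	TTTTGGTGGAAGCTCCGGACTAT	forward	23	1	0
F14	TAATGGTTGAAGCACC[I]GAC[CT]AT	forward	23	2	1
F15	TCATCGTCGA[GA]GC[I]CC[I]GA[CT]TA	forward	22	4	2
F16n	ATCGTCGAGGC[I]CC[GC]GACC	forward	19	2	1
R1	CCGAAGCCGTAGACGTTGTC	reverse	20	1	0
R2	CCGTAACCGTAGATGTTGTC[I]A	reverse	22	1	0
R3	CCG[AT]AGCCGTA[GC][GC]TGTTGTC	reverse	20	8	3
R4	CCGTATCCATACCAGTTATCCGTA	reverse	24	1	0
R5	CCAAATCCATACCAGTTATCACAGT	reverse	25	1	0
R6	CCAAAACCATACCAGTTATCAACATC	reverse	26	1	0
R7	CCATCCATACCAGTT[AG]TC[I]AC[AG]TC	reverse	24	4	2
R8	CCR[AT]A[I]CCGTAGACGTTGTC	reverse	20	4	1
R9	CCGAAGCCGTACCA[AG]TT[AG]TC	reverse	20	4	2
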