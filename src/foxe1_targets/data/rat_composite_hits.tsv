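gene	status	spacer_len	strand	sequence
Tm4sf1	down	29	-1	GGATGTTTCTCACATCCTACTACAGGGTTTCGTTGTCCCAAGGA
Etv5	down	29	1	TGATTGGTCAATGGCGCCCAACGCATAAATTATGTAAAACAGAC
Hspa5	down	10	1	GACTTGGCAGAAAAGAAAAACACTG
Casp4	down	8	-1	TTGTGTTTGCTTGTTCCCAAGAG
RT1-Da	up	11	-1	GTGTGTTTTACCAACATTTCCAAACT
Sel1l	down	11	1	GGTTTGGGAGAGCTGTTGAAACATTT
Ero1lb	down	18	-1	GAGTGTTTTCACTACATGCTAGAAAGCCAAGGC
Elovl2	up	26	-1	GTCTGTTTAGACTGAATATTAGTGCTCACATGCTCCAAGTG
Nr4a2	down	22	1	CTTTTGGAATATCCGGGAGTGTAGACCCTAAACAGCT
Dnajb9	down	18	1	TTTTTGGCCTCAGTTTTCGTAGGAGAAACAGGG
Manf	down	24	1	AGATTGGTTCGTCAATTCACGTGGTAGTTCAAAACAAGA
RT1-Da	up	29	1	GCTTTGGGGCTCAGTTTATTTTCCAGTGTCCTCAGAAAACAGCA
Bet1	down	16	1	TAATTGGACCCCATGCTCCACCCAAACAAGT
Dynlrb2	up	12	1	GGGTTGGGGGGTGAGCAACAAACAAAG
Duox2	up	26	1	TTCTTGGAGCCCCGGGCAGGGAGCGGAGAAGAGAAACAAAA
Crip	up	27	1	GCCTTGGCACCCCTCCCATGACCATGGCAACAGGAAACAACA
Hsp90b1	down	30	-1	CCCTGTTTGCATTCCGACCTGTGATAGTTAAGCGAGGCCCAAGTT
Dnajc3	down	21	1	ATCTTGGGTGTCAGAGCGGGGAGGAGTTAAACATGG
Sec23b	down	6	1	TTTTTGGATGTCTAAACATGT
Engase	down	24	1	TGCTTGGGGCCTCATAAAGCTCAAAGCCTGTAAACAGTA
Cdh1	up	10	1	TACTTGGGCTGGAAAACAAACAAAA
Slit1	up	28	-1	GAGTGTTTCTTAATTTTTCATCTATAACTACTTAGCCCAACTA
Tmem140	up	23	-1	TAGTGTTTCTGGGAGCTGTCTACAGTCTTTCCCAAGCT
Creld2	down	28	-1	AAGTGTTTATCTGATGTAATGAGGCCTACTTGTAAACCAAAGA
Duox2	up	27	-1	CGGTGTTTATCAGGCTCTGCAGGAGCCGCTACTCCCCAACGC
Hyou1	down	23	-1	AGGTGTTTGACAGGTACAGTGCTGTGGTGTGCCAATTA
Ctgf	down	11	1	TTCTTGGTGTTGTGCTGGAAACACAA
Slit1	up	23	1	ATCTTGGAGGGTCATGATGGGGATGATAGGAAACAAAG
Tmem140	up	29	1	GCTTTGGGACACATTGTTCTTCAGAAGGAGGCAGACAAACAAAA
Ankrd37	down	30	1	CAGTTGGTATAAAGAGCCATGTAAGAATTTCCAGGAAAAACATAC
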