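id	sequence	rpm	detected_in	alternative	start
PIR54042	CCCCCCACTGCTAAATTTGACTGGCT	2295.39	40	RNAY4	67
PIR2888	GGCTGGTCCGAAGGTAGTGAGTTATCTCA	1684.62	40	RNAY1	1
PIR58596	GCTAAACCTAGCCCCAAACCCACTCCACCC	1604.31	40	MT_rRNA 16S	1
PIR43376	CAGAGTGTAGCTTAACACAAAGCACCCAACT	327.78	40	MT_tRNA-Val	1
PIR57581	GAGAAAGCTCACAAGAACTGCTAACTCATG	312.29	39	MT_tRNA-Ser	1
PIR54043	CCCCCCACTGCTAAATTTGACTGGT	59.41	40	RNAY4	67
PIR59288	GGGGGGTGTAGCTCAGTGGTAGAGCGCGTGC	57.53	33	tRNA-AlaCGC	1
PIR40304	TGAATCTGACAACAGAGGCTTACGACCCCTT	44.88	40	MT_tRNA-His	32
PIR41574	TGAGATGCGGGAGCTCCGGCGCACACACTC	41.07	40	piRNACluster Chr5
PIR227919	AGTAAGGTCAGCTAATTAAG	34.69	40	MT_tRNA-Met	1
PIR75448	GGCCGGTTAGCTCAGTAGGTTAGAGCTTGG	33.04	40	tRNA-IleAAT	1
PIR45809	TGCCCCCATGTCTAACAACATGGCTTTCTC	28.77	34	MT_tRNA-Ser	29
PIR57849	GAGGGCGTGATCATGAAAGGTGATAAGCTCT	26.67	20	CDS: MT_CO2	Antisense
PIR57322	GACAACAACGGCGGCCGTGACTATGC	20.9	36	CDS: PPP1R3E	Sense, exon
PIR59786	GTTTAGACGGGCTCACATCACCCCATAAAC	18.06	30	MT_tRNA-Phe	3' END
PIR37665	TCCTGTATTTGCCGAATTGTGGTGTTT	17.91	23	piRNACluster Chr11
PIR52755	TGTGCAGAATATTGGTCGAGTTATAAGAG	17.16	35	CDS: SPATA31D1	Sense, exon
PIR55478	TTCCAGTGCCGAAGACATTGTCAGTCTGT	17.05	18	CDS: C6orf89	Sense, exon
PIR33872	TCAAGGCTAAATCTGCTCATGTCGCCACTG	16.74	33	CDS: VKORC1L1	Sense, exon
PIR31112	AAATGTTGGTTATACCCTTCCCGTACTAC	15.99	34	MT_tRNA-Met	3' END
PIR49916	TGGGAGTGAAATCAGTGTTTAGGACTA	15.85	31	piRNACluster Chr6
PIR59752	GTTAAGATGGCAGAGCCCGGTAATCGCATA	13.49	33	MT_tRNA-Leu	1
PIR59421	GGTTAGTTTTACCCTACTGATGATGTGTTGT	12.25	27	rRNA_28S	4549
PIR51124	TGGTCGTGGTTGTAGTCCGTGCGAGA	11.73	20	MT_tRNA-Glu	41
PIR1340	AGGTCAGCTAATTAAGCTATCGGGCCCATA	10.51	33	MT_tRNA-Met	5
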