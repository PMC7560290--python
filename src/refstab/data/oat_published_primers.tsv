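name	forward	reverse	amplicon_length	efficiency_percent	n_copies
PP2A	GCCCTGAGCCTACAAGAACGG	GCTGAGCGAACATGCTGAGAT	196	100.4	1
UBQ10	GATCTCAGCTCTAGCGAATCTCC	ATCCCTTCCTTGTCTTGAATCTTG	136	94.2	1
EF1A	GTGAAGATGATTCCCACCAAGC	CCTCATGTCACGCACAGCAAA	87	96.0	1
HNR	ATTGGGTTTGTCACTTTCCGTAG	CTTGGAGGGTGTCTCGCATCT	134	101.5	1
EP	GCACAAGTGATGCCAGAATAGC	CGAGATGCATTAGATTCGTTGG	193	112.4	1
TBC	TCCTCTTTCACCTCCCGATTAC	CAGATGCTTGCCCTTCTACCTC	98	92.7	1
EIF4A	TCTCGCAGGATACGGATGTCG	TCCATCGCATTGGTCGCTCT	88	100.8	1
18S	TTCTTAGTTGGTGGAGCGATTT	CCTGTTATTGCCTCAAACTTCC	150	100.4	2
GAPDH1	CTTCAACATCATTCCCAGCAG	GCCTTGGCGTCAAAGATGCT	288	110.7	2
TUA6	CCCAACAATGTGAAGTCCAGC	TGAACTGCTCACTCACCCTCC	121		3
UBC21	GCCCATCGGAGACACCTTTTG	CCTGTCTTGAAGTGAACATTTGG	133	97.8	4
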