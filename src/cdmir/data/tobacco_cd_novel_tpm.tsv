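name	sequence	length	tpm_G_ctl	tpm_G_cd	tpm_Y_ctl	tpm_Y_cd	printed_fc_G	printed_fc_Y
novel-miR17	CGTCTCCTTGATTGTGGTAGGC	22	3.2	3.4	0.0	3.3	dash	up
novel-miR18	AAGGATTCAAGGTAGAGCTGCTT	23	1.8	1.9	0.0	1.1	dash	up
novel-miR19	TATTTGTAGGAAAAGGTTACCT	22	1.5	0.0	1.7	0.0	down	down
novel-miR20	CAGGATAAGTATGTTGGAACTCC	23	1.5	0.7	0.0	0.0	dash	dash
novel-miR21	ACGAGGTTCGGACAAGTTGCA	21	0.8	0.8	0.0	0.4	dash	up
novel-miR22	CAACATGTGGAAGATCTTAGCA	22	0.8	0.8	0.0	0.9	dash	up
novel-miR23	AACCAAGGATATGTAGGCAGCT	22	0.8	0.0	0.0	0.0	down	dash
novel-miR24	TCCAGCGGCTGGAAGAGCAC	20	0.0	0.0	18.3	8.7	dash	dash
novel-miR25	TATTATGCTGGACCGGTATACT	22	0.0	0.0	3.6	0.0	dash	down
novel-miR26	TGAGTGTGAGGCGTTGGATTGA	22	0.0	2.8	3.1	3.0	up	dash
novel-miR27	CCGTCTCCTTGATTGTGGTAGG	22	0.0	0.0	3.1	0.0	dash	down
novel-miR28	ATAATATACTGGAGATTGGAGCC	23	0.0	0.0	0.9	0.4	dash	dash
novel-miR29	AGAGAGACTGTTTCCGATAGACC	23	0.0	0.0	0.0	7.0	dash	up
novel-miR30	GTGAGCATACCTGTCGGGACCC	22	0.0	0.0	0.0	12.7	dash	up
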