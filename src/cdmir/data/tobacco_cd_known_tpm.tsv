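family	name	sequence	length	tpm_G_ctl	tpm_G_cd	tpm_Y_ctl	tpm_Y_cd	printed_fc_G	printed_fc_Y
miR166	nta-miR166a	UCGGACCAGGCUUCAUUCCCC	21	49481.3	17265.8	51937.0	6379.0	-1.5	-3.1
miR166	nta-miR166b	UCGGACCAGGCUUCAUUCCCC	21	49978.8	17303.7	51466.5	6467.4	-1.5	-3.0
miR166	nta-miR166c	UCGGACCAGGCUUCAUUCCCC	21	49723.1	17629.6	51621.0	6216.5	-1.5	-3.1
miR166	nta-miR166d	UCGGACCAGGCUUCAUUCCCC	21	49377.6	17569.0	51649.1	6725.6	-1.5	-3.0
miR166	nta-miR166e	UCGGACCAGGCUUCAUUCCCC	21	49636.7	17318.9	52232.0	6618.6	-1.5	-3.0
miR166	nta-miR166f	UCGGACCAGGCUUCAUUCCCC	21	50676.6	18054.1	52246.0	6390.7	-1.5	-3.1
miR166	nta-miR166g	UCGGACCAGGCUUCAUUCCCC	21	50369.1	17152.1	53095.9	6446.0	-1.6	-3.1
miR166	nta-miR166h	UCGGACCAGGCUUCAUUCCCC	21	49450.2	17091.5	53404.9	6560.9	-1.5	-3.1
miR6149	nta-miR6149a	UUGAUACGCACCUGAAUCGGC	21	23011.6	8535.6	24061.7	5060.5	-1.5	-2.3
miR156	nta-miR156g	UGACAGAAGAUAGAGAGCAC	20	317.8	897.3	955.2	575.1	1.5	-0.7
miR156	nta-miR156i	UGACAGAAGAUAGAGAGCAC	20	317.8	952.7	870.9	580.7	1.6	-0.6
miR169	nta-miR169t	UAGCCAAGGAUGACUUGCCUU	21	925.9	2908.5	1826.0	4490.4	1.7	1.3
miR482	nta-miR482c	UUUCCAAUUCCACCCAUUCCUA	22	839.5	2476.3	962.2	2531.9	1.6	1.4
miR482	nta-miR482d	UUCCCGACUCCCCCCAUACCAC	22	13818.7	53137.0	36640.4	95327.1	1.9	1.4
miR6019	nta-miR6019a	UACAGGUGACUUGUAAAUGUUU	22	715.1	2459.1	1320.4	1770.4	1.8	0.4
miR6019	nta-miR6019b	UACAGGUGACUUGUAAAUGUUU	22	677.1	2155.5	1116.7	1426.0	1.7	0.4
miR6025	nta-miR6025a	UACCAACAAUUGAGAUAACAUC	22	894.8	3582.3	1524.0	2315.0	2.0	0.6
miR6025	nta-miR6025b	UGCCAACUAUUGAGAUGACAUC	22	666.8	2147.0	884.9	1614.2	1.7	0.9
miR6025	nta-miR6025e	UGCCAAUUAUAGAGAUGACAUC	22	739.3	2139.2	1179.9	1384.9	1.5	0.2
miR6158	nta-miR6158b	AAGUUCGAUUUGUACGAAGGGC	22	1402.6	3871.7	1474.9	3827.0	1.5	1.4
miR6158	nta-miR6158c	AAGUUCGAUUUGUACGAAGGGC	22	1433.7	3949.0	1503.0	3964.5	1.5	1.4
miR6161	nta-miR6161d	UGAACUCCAGCAUAUUAUACU	21	863.7	2632.0	1812.0	2213.5	1.6	0.3
miR159	nta-miR159	UUUGGAUUGAAGGGAGCUCUA	21	49940.8	22774.7	41676.0	9735.2	-1.1	-2.1
miR319	nta-miR319a	UUGGACUGAAGGGAGCUCCCU	21	7914.7	5074.6	17565.2	3011.8	-0.6	-2.5
miR319	nta-miR319b	UUGGACUGAAGGGAGCUCCCU	21	8246.3	4740.4	16919.0	2893.1	-0.8	-2.6
miR396	nta-miR396a	UUCCACAGCUUUCUUGAACUG	21	6356.6	4040.3	11174.0	2444.9	-0.7	-2.2
miR6145	nta-miR6145e	AUUGUUACAUGUAGCACUGGC	21	18468.7	11841.6	16954.2	5620.0	-0.6	-1.6
miR6149	nta-miR6149b	UUGAUACGCACCUGAAUCGGC	21	22994.3	8633.4	23563.0	5245.0	-1.4	-2.2
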