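patient_id	precursor_stage	gender	age_precursor_dx	age_mm_dx	ttp_months	n_serial_samples	passed_through_smm	precursor_mut	mm_mut	first_precursor_negative	genes
1	MGUS	F	72	73	6	2	0	nd	nd	0
2	SMM	F	85	86	12	2	0	X	X	0	ARID2,RASA2,IKBK,XBP1,KRAS
3	MGUS	F	80	81	15	3	0	X	X	0	FAM46C,BCL7A
4	MGUS	M	56	58	23	2	0	X	X	0	KRAS
5	MGUS	M	78	80	24	2	0	X	X	0	DNMT3A
6	SMM	M	74	76	25	2	0	X	X	0	KRAS
7	MGUS	F	67	70	39	2	0	nd	nd	0
8	MGUS	F	80	84	50	3	0	X	X	0	DIS3
9	MGUS	M	68	73	54	2	0	nd	nd	0
10	MGUS	M	65	71	68	3	0	X	X	1	NRAS
11	MGUS	F	56	62	72	2	0	X	X	0	TP53,HIST1HE
12	MGUS	M	67	73	78	6	1	X	X	0	PTPN11
13	MGUS	M	64	71	85	2	0	X	X	0	SP140,KRAS
14	MGUS	F	70	77	86	7	1	X	X	0	SETD2,FAM46C,KRAS
15	MGUS	F	54	61	87	6	1	X	X	1	NRAS
16	MGUS	M	62	70	91	4	1	X	X	0	PTPN11,MAX
17	MGUS	F	54	63	103	5	0	X	X	0	IDH1
18	MGUS	F	69	77	103	3	1	X	X	0	IRF4,HISTH1D
19	MGUS	M	50	59	105	2	0	nd	nd	0
20	MGUS	M	67	77	121	6	1	X	X	1	BRAF
21	MGUS	M	62	76	166	2	0	nd	X	0	BCL7A,KRAS
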