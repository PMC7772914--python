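dataset	caller	n_calls	tp	fp	tn	fn	tpr	ppv	f1
P1	SNVQ	5154	48	114	0	0	100	29.63	45.71
P1	Strelka	435	48	34	80	0	100	58.54	73.85
P1	2CP	65	41	8	106	7	85.42	83.67	84.54
P1	PLATO	587	42	6	104	10	80.77	87.5	84
P2	SNVQ	597	147	65	3	2	98.66	69.34	81.44
P2	Strelka	619	149	59	9	0	100	71.63	83.47
P2	2CP	187	133	39	29	16	89.26	77.33	82.87
P2	PLATO	449	144	43	25	5	96.64	77.01	85.71
P3	SNVQ	629	61	13	8	1	98.39	82.43	89.71
P3	Strelka	306	62	11	10	0	100	84.93	91.85
P3	2CP	76	57	1	20	5	91.94	98.28	95
P3	PLATO	429	62	3	18	0	100	95.38	97.64
P4	SNVQ	482	48	23	87	2	96	67.61	79.34
P4	Strelka	380	50	94	16	0	100	34.72	51.55
P4	2CP	67	45	2	108	5	90	95.74	92.78
P4	PLATO	490	48	7	103	2	96	87.27	91.43
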