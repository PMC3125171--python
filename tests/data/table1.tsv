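gene_id	fc	function	class	fpr1	fmr1
Pa_4_3858	48.16	unknown function	4	A	0
Pa_1_24410	27.87	SAM-dependent methyltransferase	4	A	0
Pa_5_3435	7.76	unknown function	4	A	0
Pa_5_9770	5.96	Asp protease	4	A	0
Pa_2_13290	3.42	unknown function	4	A	0
Pa_1_16335	3.28	unknown function	5	0	R
Pa_4_9360	2,67	fructose-1,6-bisphosphatase	8	0	0
Pa_2_8800	2,64	unknown function	4	A	0
Pa_6_9980	2,53	unknown function	8	A	0
Pa_5_11640	2,34	ABC transporter	8	0	0
Pa_7_2870	2,31	unknown function	4	A	0
Pa_1_20510	2,05	sugar transporter	2	A	R
Pa_2_7590	2,02	unknown function	8	0	0
Pa_3_10430	-2,08	unknown function	8	0	0
Pa_1_6014	-2,62	unknown function	1	0	0
Pa_4_1433	-2,64	unknown function	8	0	0
Pa_3_10350	-3,61	unknown function	8	0	0
Pa_6_10330	-3,91	polyketide synthase	5	0	A
Pa_4_1290	-5,05	carbohydrate esterase	5	0	A
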