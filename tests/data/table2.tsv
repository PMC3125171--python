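gene_id	fc_fpr1_side	fc_fmr1_side	function	class	fpr1	fmr1
Pa_2_4890	3.93	3.61	taurine catabolism dioxygenase	9	A	A
Pa_5_4645	3.46	3.4	NUDIX domain-containing protein	9	A	A
Pa_5_11800	3.08	2.85	MFS transporter	9	A	A
Pa_2_610	2.52	2.28	geranylgeranyl diphosphate synthase	9	A	A
Pa_0_495	2.33	2.05	unknown function	9	A	A
Pa_2_4855	2.08	2.39	unknown function	9	A	A
Pa_4_4010	2.07	2.39	nucleoside hydrolase	9	A	A
Pa_5_6710	-2.28	-2.17	unknown function	9	R	R
Pa_7_10775	-2.27	-2.9	unknown function	9	R	R
Pa_6_6690	-2.2	-2.09	acetyl transferase	9	R	R
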