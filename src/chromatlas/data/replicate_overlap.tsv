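species	tissue	repA_peaks	repB_peaks	a_overlap_b	pct_a_printed	b_overlap_a	pct_b_printed
cattle	Adipose	59612	133768	38647	64.8	38471	28.8
cattle	Brain Cortex	109395	160546	75462	69.0	75206	46.8
cattle	Hypothalamus	59966	37036	19970	33.3	19999	54.0
cattle	Liver	102704	114583	58444	56.9	58563	51.1
cattle	Lung	221576	248844	167311	75.5	166777	67.0
cattle	Muscle	107208	113502	76780	71.6	76801	67.7
cattle	Spleen	110852	200323	79355	71.6	79007	39.4
pig	Adipose	9192	7645	4778	52.0	4778	62.5
pig	Cerebellum	220327	214455	132123	60.0	132292	61.7
pig	Brain Cortex	142658	156069	103581	72.6	103382	66.2
pig	Hypothalamus	103402	144418	63382	61.3	63368	43.9
pig	Liver	112202	136085	78395	69.9	78274	57.5
pig	Lung	167298	191926	114470	68.4	113864	59.3
pig	Muscle	137000	105823	92039	67.2	92705	87.6
pig	Spleen	100982	100867	64192	63.6	64208	63.7
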