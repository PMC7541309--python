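species	tissue	replicate	raw_reads	mapped_reads	duplicate_reads	informative_reads	pct_raw_printed
cattle	Adipose	A	152184070	145648161	82972324	37815392	24.85
cattle	Adipose	B	126920776	123879749	25466938	72623985	57.22
cattle	Cerebellum	B	158964554	134391900	53303886	49305250	31.02
cattle	Brain Cortex	A	216202716	189763599	122567574	30997045	14.34
cattle	Brain Cortex	B	205363760	174961995	96411128	41021487	19.98
cattle	Hypothalamus	A	146439048	102771471	50044176	35090140	23.96
cattle	Hypothalamus	B	68153356	63771723	31495325	15328535	22.49
cattle	Liver	A	175124072	165112503	95001248	40031560	22.86
cattle	Liver	B	194367992	179265341	99942567	36472289	18.76
cattle	Lung	A	163469102	159710295	27682063	99691291	60.98
cattle	Lung	B	190030170	184571092	36657121	110584502	58.19
cattle	Muscle	A	89174618	86045857	15262767	55794693	62.57
cattle	Muscle	B	97247280	69592640	10539048	45909945	47.21
cattle	Spleen	A	261785316	250911567	163860741	37521241	14.33
cattle	Spleen	B	179854284	162449025	51533284	69626100	38.71
pig	Adipose	A	93118998	87025520	15814107	57651677	61.91
pig	Adipose	B	71639956	66597412	12368404	42960583	59.97
pig	Cerebellum	A	186388542	175280070	90013906	63538783	34.09
pig	Cerebellum	B	125817350	116536743	41557703	57997395	46.10
pig	Brain Cortex	A	101924240	98384411	36110627	53096952	52.09
pig	Brain Cortex	B	160871726	155783257	77377043	66403810	41.28
pig	Hypothalamus	A	112463726	106966835	52803730	39919895	35.50
pig	Hypothalamus	B	170163006	162907052	92303710	56125160	32.98
pig	Liver	A	171864386	167321556	113588699	42376220	24.66
pig	Liver	B	169952062	164205920	85279200	64117458	37.73
pig	Lung	A	108086464	104424556	19658156	73018749	67.56
pig	Lung	B	110690180	106275981	17791030	74869852	67.64
pig	Muscle	A	168211474	165225305	41747860	113058649	67.21
pig	Muscle	B	141069686	138785466	39577315	91780486	65.06
pig	Spleen	A	91549652	88698199	13254769	64352893	70.29
pig	Spleen	B	93747292	90558895	12817045	67241934	71.73
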