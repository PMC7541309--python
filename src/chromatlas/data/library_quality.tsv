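species	tissue	replicate	nrf	frip	sjsd
cattle	Adipose	A	0.43	9.82	0.34
cattle	Adipose	B	0.79	15.04	0.34
cattle	Cerebellum	B	0.60	42.53	0.48
cattle	Brain Cortex	A	0.35	30.16	0.48
cattle	Brain Cortex	B	0.45	40.80	0.49
cattle	Hypothalamus	A	0.51	43.67	0.50
cattle	Hypothalamus	B	0.51	11.97	0.37
cattle	Liver	A	0.42	37.99	0.50
cattle	Liver	B	0.44	28.17	0.44
cattle	Lung	A	0.83	37.63	0.45
cattle	Lung	B	0.80	44.26	0.48
cattle	Muscle	A	0.82	40.77	0.50
cattle	Muscle	B	0.85	41.77	0.51
cattle	Spleen	A	0.35	21.29	0.42
cattle	Spleen	B	0.68	35.24	0.45
pig	Adipose	A	0.82	5.21	0.40
pig	Adipose	B	0.81	4.12	0.40
pig	Cerebellum	A	0.49	43.05	0.46
pig	Cerebellum	B	0.64	41.49	0.47
pig	Brain Cortex	A	0.63	40.65	0.48
pig	Brain Cortex	B	0.50	44.53	0.46
pig	Hypothalamus	A	0.51	36.85	0.49
pig	Hypothalamus	B	0.43	37.76	0.44
pig	Liver	A	0.32	55.38	0.52
pig	Liver	B	0.48	49.25	0.49
pig	Lung	A	0.81	31.21	0.43
pig	Lung	B	0.83	36.87	0.46
pig	Muscle	A	0.75	58.16	0.62
pig	Muscle	B	0.71	61.94	0.65
pig	Spleen	A	0.85	29.41	0.43
pig	Spleen	B	0.86	22.70	0.38
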