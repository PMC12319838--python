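category	group	train_reject	train_accept	test_reject	test_accept
Controls	ADNI	13	252	2	71
Controls	OPDC	8	66	2	14
Controls	Whitehall 1	35	407	9	101
Controls	Whitehall 2	6	173	1	43
Patients	ADNI Dementia	16	148	2	26
Patients	ADNI MCI	11	459	3	117
Patients	OPDC RBD	16	81	4	23
Patients	OPDC iPD	22	113	6	27
Patients	BHC	12	116	4	28
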