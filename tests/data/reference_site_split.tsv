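site	train_reject	train_accept	test_reject	test_accept	visual_accept_pct
ADNI GE 1.5T	8	172	1	43	96
ADNI GE 3T	4	16	0	4	83.3
ADNI Philips 1.5T	1	49	0	12	98.4
ADNI Philips 3T	7	153	2	38	95.5
ADNI Siemens 3T	8	332	2	83	97.6
ADNI Siemens 1.5T	10	128	2	32	93
ADNI Siemens 2.9T	2	9	0	2	84.6
OPDC Siemens 3T	47	260	12	64	84.6
BHC Siemens 3T	12	116	4	28	90
Whitehall 1 Siemens 3T	35	407	9	101	92
Whitehall 2 Siemens 3T	6	173	1	43	96.9
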