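stratum	fn	fp	tp	tn	printed_ppa	printed_ppa_lo	printed_ppa_hi	printed_npa	pool_consistent	fp_caveat
All compiled	76	201	29475	45847148	99.74	99.68	99.81	100	1	0
P/LP variants only	0	0	145	28474503	100	100	100	100	1	0
SNVs only	23	6	28710	45848108	99.92	99.87	99.97	100	1	0
Insertions only	9	8	225	29887204	96.20	94.30	98.00	100	0	0
Deletions only	33	12	540	42170158	94.24	92.65	95.83	100	1	0
Segmental duplications	12	22	2119	38466267	99.44	99.10	99.78	100	1	0
Known pseudogenes	9	74	1075	45676596	99.17	98.60	99.73	100	1	0
Low mappability regions	18	12	1069	36912107	98.34	97.84	98.85	100	1	0
Low complexity regions	24	69	956	38072735	97.55	96.35	98.75	100	1	0
Low GC regions	6	12	197	14792575	97.04	95.87	98.22	100	1	0
High GC regions	0	0	23	3891553	100	100	100	100	1	0
Heterozygous variants only	75	147	18295	45858382	99.59	98.48	99.70	100	1	1
Homozygous variants only	1	83	11180	45865561	99.99	99.97	100	100	1	1
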