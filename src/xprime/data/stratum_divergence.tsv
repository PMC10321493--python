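stratum	length_mb	n_homologs	dxy	neutral_midpoint_ma
S1	9.00	326	0.0075	0.147
S2	0.50	15	0.0040	0.098
S3	23.80	904	0.0123	0.221
S4	1.00	35	0.0039	0.067
S5	1.65	55	0.0151	0.292
S6	0.10	2	0.0074	0.099
S7	9.40	350	0.0145	0.290
S8	0.10	0	0.0006	NA
S9	2.55	62	0.0153	0.318
S10	0.40	22	0.0122	0.233
S11	1.50	50	0.0145	0.277
S12	1.90	96	0.0159	0.335
S13	1.30	90	0.0136	0.260
S14	1.20	36	0.0104	0.286
S15	3.50	97	0.0096	0.147
S16	0.95	54	0.0093	0.200
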