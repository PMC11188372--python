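chemical	2,3-Benzofluorene	2,3-Benzofluorene	2,3-Benzofluorene	2,3-Benzofluorene	2,3-Benzofluorene	2,3-Benzofluorene	6:1 FTOH	6:1 FTOH	6:1 FTOH	6:1 FTOH	6:1 FTOH	6:1 FTOH
sex	female	female	female	male	male	male	female	female	female	male	male	male
dose_mg_per_kg	12.0	111.0	1000.0	12.0	111.0	1000.0	12.0	111.0	1000.0	12.0	111.0	1000.0
mie												
Ahr	0	0	4	2	4	4	0	1	4	1	4	4
Esr1	0	0	0	0	0	1	0	0	0	0	0	0
Hnf4a	0	3	6	0	6	6	0	4	6	0	4	6
Nr3c1	0	1	2	0	2	2	0	1	2	0	1	2
Ppara	0	1	1	0	2	1	0	6	8	3	6	8
Srebf1	0	1	1	0	1	1	0	1	1	0	2	2
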