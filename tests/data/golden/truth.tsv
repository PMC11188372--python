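gene	chemical	dose_mg_per_kg	sex	effect
Acadm	6:1 FTOH	12.000000	female	0.312596
Acadm	6:1 FTOH	12.000000	male	0.312596
Acadm	6:1 FTOH	111.000000	female	1.049558
Acadm	6:1 FTOH	111.000000	male	1.049558
Acadm	6:1 FTOH	1000.000000	female	2.000000
Acadm	6:1 FTOH	1000.000000	male	2.000000
Acox1	6:1 FTOH	12.000000	female	0.312596
Acox1	6:1 FTOH	12.000000	male	0.312596
Acox1	6:1 FTOH	111.000000	female	1.049558
Acox1	6:1 FTOH	111.000000	male	1.049558
Acox1	6:1 FTOH	1000.000000	female	2.000000
Acox1	6:1 FTOH	1000.000000	male	2.000000
Aldh1a1	2,3-Benzofluorene	12.000000	female	0.234447
Aldh1a1	2,3-Benzofluorene	12.000000	male	0.234447
Aldh1a1	2,3-Benzofluorene	111.000000	female	0.787168
Aldh1a1	2,3-Benzofluorene	111.000000	male	0.787168
Aldh1a1	2,3-Benzofluorene	1000.000000	female	1.500000
Aldh1a1	2,3-Benzofluorene	1000.000000	male	1.500000
Aldh1a1	6:1 FTOH	12.000000	female	-0.234447
Aldh1a1	6:1 FTOH	12.000000	male	-0.234447
Aldh1a1	6:1 FTOH	111.000000	female	-0.787168
Aldh1a1	6:1 FTOH	111.000000	male	-0.787168
Aldh1a1	6:1 FTOH	1000.000000	female	-1.500000
Aldh1a1	6:1 FTOH	1000.000000	male	-1.500000
Angptl4	6:1 FTOH	12.000000	female	0.312596
Angptl4	6:1 FTOH	12.000000	male	0.312596
Angptl4	6:1 FTOH	111.000000	female	1.049558
Angptl4	6:1 FTOH	111.000000	male	1.049558
Angptl4	6:1 FTOH	1000.000000	female	2.000000
Angptl4	6:1 FTOH	1000.000000	male	2.000000
Apoa1	2,3-Benzofluorene	12.000000	female	0.234447
Apoa1	2,3-Benzofluorene	12.000000	male	-0.234447
Apoa1	2,3-Benzofluorene	111.000000	female	0.787168
Apoa1	2,3-Benzofluorene	111.000000	male	-0.787168
Apoa1	2,3-Benzofluorene	1000.000000	female	1.500000
Apoa1	2,3-Benzofluorene	1000.000000	male	-1.500000
Apoa1	6:1 FTOH	12.000000	female	0.547043
Apoa1	6:1 FTOH	12.000000	male	0.078149
Apoa1	6:1 FTOH	111.000000	female	1.836726
Apoa1	6:1 FTOH	111.000000	male	0.262389
Apoa1	6:1 FTOH	1000.000000	female	3.500000
Apoa1	6:1 FTOH	1000.000000	male	0.500000
Apoa5	6:1 FTOH	12.000000	female	0.312596
Apoa5	6:1 FTOH	12.000000	male	0.312596
Apoa5	6:1 FTOH	111.000000	female	1.049558
Apoa5	6:1 FTOH	111.000000	male	1.049558
Apoa5	6:1 FTOH	1000.000000	female	2.000000
Apoa5	6:1 FTOH	1000.000000	male	2.000000
Cpt2	6:1 FTOH	12.000000	female	0.312596
Cpt2	6:1 FTOH	12.000000	male	0.312596
Cpt2	6:1 FTOH	111.000000	female	1.049558
Cpt2	6:1 FTOH	111.000000	male	1.049558
Cpt2	6:1 FTOH	1000.000000	female	2.000000
Cpt2	6:1 FTOH	1000.000000	male	2.000000
Cyp1a1	2,3-Benzofluorene	12.000000	female	0.234447
Cyp1a1	2,3-Benzofluorene	12.000000	male	0.234447
Cyp1a1	2,3-Benzofluorene	111.000000	female	0.787168
Cyp1a1	2,3-Benzofluorene	111.000000	male	0.787168
Cyp1a1	2,3-Benzofluorene	1000.000000	female	1.500000
Cyp1a1	2,3-Benzofluorene	1000.000000	male	1.500000
Cyp1a1	6:1 FTOH	12.000000	female	-0.234447
Cyp1a1	6:1 FTOH	12.000000	male	-0.234447
Cyp1a1	6:1 FTOH	111.000000	female	-0.787168
Cyp1a1	6:1 FTOH	111.000000	male	-0.787168
Cyp1a1	6:1 FTOH	1000.000000	female	-1.500000
Cyp1a1	6:1 FTOH	1000.000000	male	-1.500000
Cyp1a2	2,3-Benzofluorene	12.000000	female	0.234447
Cyp1a2	2,3-Benzofluorene	12.000000	male	0.234447
Cyp1a2	2,3-Benzofluorene	111.000000	female	0.787168
Cyp1a2	2,3-Benzofluorene	111.000000	male	0.787168
Cyp1a2	2,3-Benzofluorene	1000.000000	female	1.500000
Cyp1a2	2,3-Benzofluorene	1000.000000	male	1.500000
Cyp1a2	6:1 FTOH	12.000000	female	-0.234447
Cyp1a2	6:1 FTOH	12.000000	male	-0.234447
Cyp1a2	6:1 FTOH	111.000000	female	-0.787168
Cyp1a2	6:1 FTOH	111.000000	male	-0.787168
Cyp1a2	6:1 FTOH	1000.000000	female	-1.500000
Cyp1a2	6:1 FTOH	1000.000000	male	-1.500000
Cyp4a1	6:1 FTOH	12.000000	female	0.312596
Cyp4a1	6:1 FTOH	12.000000	male	0.312596
Cyp4a1	6:1 FTOH	111.000000	female	1.049558
Cyp4a1	6:1 FTOH	111.000000	male	1.049558
Cyp4a1	6:1 FTOH	1000.000000	female	2.000000
Cyp4a1	6:1 FTOH	1000.000000	male	2.000000
Cyp7a1	2,3-Benzofluorene	12.000000	female	0.234447
Cyp7a1	2,3-Benzofluorene	12.000000	male	-0.234447
Cyp7a1	2,3-Benzofluorene	111.000000	female	0.787168
Cyp7a1	2,3-Benzofluorene	111.000000	male	-0.787168
Cyp7a1	2,3-Benzofluorene	1000.000000	female	1.500000
Cyp7a1	2,3-Benzofluorene	1000.000000	male	-1.500000
Cyp7a1	6:1 FTOH	12.000000	female	0.234447
Cyp7a1	6:1 FTOH	12.000000	male	-0.234447
Cyp7a1	6:1 FTOH	111.000000	female	0.787168
Cyp7a1	6:1 FTOH	111.000000	male	-0.787168
Cyp7a1	6:1 FTOH	1000.000000	female	1.500000
Cyp7a1	6:1 FTOH	1000.000000	male	-1.500000
G0s2	2,3-Benzofluorene	12.000000	female	0.234447
G0s2	2,3-Benzofluorene	12.000000	male	-0.234447
G0s2	2,3-Benzofluorene	111.000000	female	0.787168
G0s2	2,3-Benzofluorene	111.000000	male	-0.787168
G0s2	2,3-Benzofluorene	1000.000000	female	1.500000
G0s2	2,3-Benzofluorene	1000.000000	male	-1.500000
G0s2	6:1 FTOH	12.000000	female	0.234447
G0s2	6:1 FTOH	12.000000	male	-0.234447
G0s2	6:1 FTOH	111.000000	female	0.787168
G0s2	6:1 FTOH	111.000000	male	-0.787168
G0s2	6:1 FTOH	1000.000000	female	1.500000
G0s2	6:1 FTOH	1000.000000	male	-1.500000
Hmgcs2	6:1 FTOH	12.000000	female	0.312596
Hmgcs2	6:1 FTOH	12.000000	male	0.312596
Hmgcs2	6:1 FTOH	111.000000	female	1.049558
Hmgcs2	6:1 FTOH	111.000000	male	1.049558
Hmgcs2	6:1 FTOH	1000.000000	female	2.000000
Hmgcs2	6:1 FTOH	1000.000000	male	2.000000
Igfbp1	2,3-Benzofluorene	12.000000	female	0.234447
Igfbp1	2,3-Benzofluorene	12.000000	male	-0.234447
Igfbp1	2,3-Benzofluorene	111.000000	female	0.787168
Igfbp1	2,3-Benzofluorene	111.000000	male	-0.787168
Igfbp1	2,3-Benzofluorene	1000.000000	female	1.500000
Igfbp1	2,3-Benzofluorene	1000.000000	male	-1.500000
Igfbp1	6:1 FTOH	12.000000	female	0.234447
Igfbp1	6:1 FTOH	12.000000	male	-0.234447
Igfbp1	6:1 FTOH	111.000000	female	0.787168
Igfbp1	6:1 FTOH	111.000000	male	-0.787168
Igfbp1	6:1 FTOH	1000.000000	female	1.500000
Igfbp1	6:1 FTOH	1000.000000	male	-1.500000
Nqo1	2,3-Benzofluorene	12.000000	female	0.234447
Nqo1	2,3-Benzofluorene	12.000000	male	0.234447
Nqo1	2,3-Benzofluorene	111.000000	female	0.787168
Nqo1	2,3-Benzofluorene	111.000000	male	0.787168
Nqo1	2,3-Benzofluorene	1000.000000	female	1.500000
Nqo1	2,3-Benzofluorene	1000.000000	male	1.500000
Nqo1	6:1 FTOH	12.000000	female	-0.234447
Nqo1	6:1 FTOH	12.000000	male	-0.234447
Nqo1	6:1 FTOH	111.000000	female	-0.787168
Nqo1	6:1 FTOH	111.000000	male	-0.787168
Nqo1	6:1 FTOH	1000.000000	female	-1.500000
Nqo1	6:1 FTOH	1000.000000	male	-1.500000
Pck1	2,3-Benzofluorene	12.000000	female	0.234447
Pck1	2,3-Benzofluorene	12.000000	male	-0.234447
Pck1	2,3-Benzofluorene	111.000000	female	0.787168
Pck1	2,3-Benzofluorene	111.000000	male	-0.787168
Pck1	2,3-Benzofluorene	1000.000000	female	1.500000
Pck1	2,3-Benzofluorene	1000.000000	male	-1.500000
Pck1	6:1 FTOH	12.000000	female	0.234447
Pck1	6:1 FTOH	12.000000	male	-0.234447
Pck1	6:1 FTOH	111.000000	female	0.787168
Pck1	6:1 FTOH	111.000000	male	-0.787168
Pck1	6:1 FTOH	1000.000000	female	1.500000
Pck1	6:1 FTOH	1000.000000	male	-1.500000
Tat	2,3-Benzofluorene	12.000000	female	0.234447
Tat	2,3-Benzofluorene	12.000000	male	-0.234447
Tat	2,3-Benzofluorene	111.000000	female	0.787168
Tat	2,3-Benzofluorene	111.000000	male	-0.787168
Tat	2,3-Benzofluorene	1000.000000	female	1.500000
Tat	2,3-Benzofluorene	1000.000000	male	-1.500000
Tat	6:1 FTOH	12.000000	female	0.234447
Tat	6:1 FTOH	12.000000	male	-0.234447
Tat	6:1 FTOH	111.000000	female	0.787168
Tat	6:1 FTOH	111.000000	male	-0.787168
Tat	6:1 FTOH	1000.000000	female	1.500000
Tat	6:1 FTOH	1000.000000	male	-1.500000
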