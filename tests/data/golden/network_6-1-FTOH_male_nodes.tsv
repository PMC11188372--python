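node	node_type	log2fc	sign_class	dysregulation_class
Ppara	MIE		neutral	none
Hnf4a	MIE		neutral	none
Ahr	MIE		neutral	none
Nr3c1	MIE		neutral	none
Srebf1	MIE		neutral	none
Esr1	MIE		neutral	none
Abcc3	target	0.364533	up	none
Abcg5	target	0.077678	up	none
Acaca	target	0.037640	up	none
Acadm	target	1.865241	up	up
Acox1	target	2.493311	up	up
Aldh1a1	target	-1.788216	down	down
Angptl4	target	2.324212	up	up
Apoa1	target	0.684952	up	up
Apoa5	target	2.042272	up	up
Cdkn1a	target	-0.503264	down	none
Cpt2	target	2.110778	up	up
Cyp1a1	target	-1.747917	down	down
Cyp1a2	target	-1.215588	down	down
Cyp4a1	target	2.117718	up	up
Cyp7a1	target	-1.617564	down	down
Fads1	target	-0.663029	down	down
G0s2	target	-1.514640	down	down
Hmgcs2	target	1.547704	up	up
Igfbp1	target	-1.535023	down	down
Igfbp3	target	-0.042688	down	none
Myc	target	-0.316988	down	none
Nqo1	target	-2.168941	down	down
Pck1	target	-1.999265	down	down
Scd	target	-0.476063	down	none
Tat	target	-1.331817	down	down
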