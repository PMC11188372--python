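node	node_type	log2fc	sign_class	dysregulation_class
Ppara	MIE		neutral	none
Hnf4a	MIE		neutral	none
Ahr	MIE		neutral	none
Nr3c1	MIE		neutral	none
Srebf1	MIE		neutral	none
Esr1	MIE		neutral	none
Abcc3	target	-0.814556	down	down
Abcg5	target	0.243503	up	none
Acaca	target	0.100756	up	none
Acadm	target	-0.064307	down	none
Acox1	target	0.176215	up	none
Aldh1a1	target	0.794279	up	up
Angptl4	target	0.345371	up	none
Apoa1	target	-1.740080	down	down
Apoa5	target	0.310471	up	none
Cdkn1a	target	-0.152159	down	none
Cpt2	target	0.402234	up	none
Cyp1a1	target	2.071939	up	up
Cyp1a2	target	1.167338	up	up
Cyp4a1	target	-0.106444	down	none
Cyp7a1	target	-1.150221	down	down
Fads1	target	-0.236890	down	none
G0s2	target	-1.488934	down	down
Hmgcs2	target	0.435687	up	none
Igfbp1	target	-2.069413	down	down
Igfbp3	target	-0.075428	down	none
Myc	target	0.047379	up	none
Nqo1	target	1.633449	up	up
Pck1	target	-1.323319	down	down
Scd	target	0.234925	up	none
Tat	target	-1.427263	down	down
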