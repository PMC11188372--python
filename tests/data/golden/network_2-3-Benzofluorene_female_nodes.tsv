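node	node_type	log2fc	sign_class	dysregulation_class
Ppara	MIE		neutral	none
Hnf4a	MIE		neutral	none
Ahr	MIE		neutral	none
Nr3c1	MIE		neutral	none
Srebf1	MIE		neutral	none
Esr1	MIE		neutral	none
Abcc3	target	0.129715	up	none
Abcg5	target	-0.159128	down	none
Acaca	target	-0.332462	down	none
Acadm	target	0.267289	up	none
Acox1	target	0.081647	up	none
Aldh1a1	target	2.082367	up	up
Angptl4	target	-0.248157	down	none
Apoa1	target	1.476864	up	up
Apoa5	target	-0.219479	down	none
Cdkn1a	target	-0.030767	down	none
Cpt2	target	0.000856	up	none
Cyp1a1	target	1.643472	up	up
Cyp1a2	target	0.775664	up	up
Cyp4a1	target	0.204767	up	none
Cyp7a1	target	1.162459	up	up
Fads1	target	-0.192090	down	none
G0s2	target	1.760183	up	up
Hmgcs2	target	0.090567	up	none
Igfbp1	target	0.852956	up	up
Igfbp3	target	-0.487106	down	none
Myc	target	-0.306017	down	none
Nqo1	target	1.655726	up	up
Pck1	target	1.567618	up	up
Scd	target	0.350482	up	none
Tat	target	1.624858	up	up
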