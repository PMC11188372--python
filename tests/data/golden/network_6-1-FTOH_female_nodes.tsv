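node	node_type	log2fc	sign_class	dysregulation_class
Ppara	MIE		neutral	none
Hnf4a	MIE		neutral	none
Ahr	MIE		neutral	none
Nr3c1	MIE		neutral	none
Srebf1	MIE		neutral	none
Esr1	MIE		neutral	none
Abcc3	target	0.397841	up	none
Abcg5	target	0.090058	up	none
Acaca	target	0.202894	up	none
Acadm	target	1.847797	up	up
Acox1	target	1.219888	up	up
Aldh1a1	target	-1.279799	down	down
Angptl4	target	1.658468	up	up
Apoa1	target	3.453004	up	up
Apoa5	target	2.117321	up	up
Cdkn1a	target	0.027654	up	none
Cpt2	target	1.995342	up	up
Cyp1a1	target	-1.310121	down	down
Cyp1a2	target	-1.317302	down	down
Cyp4a1	target	2.051681	up	up
Cyp7a1	target	1.305318	up	up
Fads1	target	-0.183738	down	none
G0s2	target	1.419779	up	up
Hmgcs2	target	1.724868	up	up
Igfbp1	target	1.174343	up	up
Igfbp3	target	0.051431	up	none
Myc	target	0.388384	up	none
Nqo1	target	-1.478558	down	down
Pck1	target	1.861678	up	up
Scd	target	-0.359991	down	none
Tat	target	1.332254	up	up
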