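mie	chemical	class	sex	dose_mg_per_kg	n_up	n_down	n_total	up_genes	down_genes
Ppara	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Hnf4a	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Ahr	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Nr3c1	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Srebf1	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Esr1	2,3-Benzofluorene	PAH	female	12.000000	0	0	0		
Ppara	2,3-Benzofluorene	PAH	male	12.000000	0	0	0		
Hnf4a	2,3-Benzofluorene	PAH	male	12.000000	0	0	0		
Ahr	2,3-Benzofluorene	PAH	male	12.000000	2	0	2	Cyp1a1;Cyp1a2	
Nr3c1	2,3-Benzofluorene	PAH	male	12.000000	0	0	0		
Srebf1	2,3-Benzofluorene	PAH	male	12.000000	0	0	0		
Esr1	2,3-Benzofluorene	PAH	male	12.000000	0	0	0		
Ppara	2,3-Benzofluorene	PAH	female	111.000000	1	0	1	Apoa1	
Hnf4a	2,3-Benzofluorene	PAH	female	111.000000	3	0	3	Apoa1;Pck1;Tat	
Ahr	2,3-Benzofluorene	PAH	female	111.000000	0	0	0		
Nr3c1	2,3-Benzofluorene	PAH	female	111.000000	1	0	1	Tat	
Srebf1	2,3-Benzofluorene	PAH	female	111.000000	1	0	1	Pck1	
Esr1	2,3-Benzofluorene	PAH	female	111.000000	0	0	0		
Ppara	2,3-Benzofluorene	PAH	male	111.000000	0	2	2		Acox1;Apoa1
Hnf4a	2,3-Benzofluorene	PAH	male	111.000000	0	6	6		Apoa1;Cyp7a1;G0s2;Igfbp1;Pck1;Tat
Ahr	2,3-Benzofluorene	PAH	male	111.000000	4	0	4	Aldh1a1;Cyp1a1;Cyp1a2;Nqo1	
Nr3c1	2,3-Benzofluorene	PAH	male	111.000000	0	2	2		Igfbp1;Tat
Srebf1	2,3-Benzofluorene	PAH	male	111.000000	0	1	1		Pck1
Esr1	2,3-Benzofluorene	PAH	male	111.000000	0	0	0		
Ppara	2,3-Benzofluorene	PAH	female	1000.000000	1	0	1	Apoa1	
Hnf4a	2,3-Benzofluorene	PAH	female	1000.000000	6	0	6	Apoa1;Cyp7a1;G0s2;Igfbp1;Pck1;Tat	
Ahr	2,3-Benzofluorene	PAH	female	1000.000000	4	0	4	Aldh1a1;Cyp1a1;Cyp1a2;Nqo1	
Nr3c1	2,3-Benzofluorene	PAH	female	1000.000000	2	0	2	Igfbp1;Tat	
Srebf1	2,3-Benzofluorene	PAH	female	1000.000000	1	0	1	Pck1	
Esr1	2,3-Benzofluorene	PAH	female	1000.000000	0	0	0		
Ppara	2,3-Benzofluorene	PAH	male	1000.000000	0	1	1		Apoa1
Hnf4a	2,3-Benzofluorene	PAH	male	1000.000000	0	6	6		Apoa1;Cyp7a1;G0s2;Igfbp1;Pck1;Tat
Ahr	2,3-Benzofluorene	PAH	male	1000.000000	4	0	4	Aldh1a1;Cyp1a1;Cyp1a2;Nqo1	
Nr3c1	2,3-Benzofluorene	PAH	male	1000.000000	0	2	2		Igfbp1;Tat
Srebf1	2,3-Benzofluorene	PAH	male	1000.000000	0	1	1		Pck1
Esr1	2,3-Benzofluorene	PAH	male	1000.000000	0	1	1		Abcc3
Ppara	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Hnf4a	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Ahr	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Nr3c1	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Srebf1	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Esr1	6:1 FTOH	PFAS	female	12.000000	0	0	0		
Ppara	6:1 FTOH	PFAS	male	12.000000	3	0	3	Acox1;Apoa5;Cpt2	
Hnf4a	6:1 FTOH	PFAS	male	12.000000	0	0	0		
Ahr	6:1 FTOH	PFAS	male	12.000000	0	1	1		Nqo1
Nr3c1	6:1 FTOH	PFAS	male	12.000000	0	0	0		
Srebf1	6:1 FTOH	PFAS	male	12.000000	0	0	0		
Esr1	6:1 FTOH	PFAS	male	12.000000	0	0	0		
Ppara	6:1 FTOH	PFAS	female	111.000000	6	0	6	Acadm;Angptl4;Apoa1;Apoa5;Cpt2;Cyp4a1	
Hnf4a	6:1 FTOH	PFAS	female	111.000000	4	0	4	Apoa1;G0s2;Pck1;Tat	
Ahr	6:1 FTOH	PFAS	female	111.000000	0	1	1		Cyp1a2
Nr3c1	6:1 FTOH	PFAS	female	111.000000	1	0	1	Tat	
Srebf1	6:1 FTOH	PFAS	female	111.000000	1	0	1	Pck1	
Esr1	6:1 FTOH	PFAS	female	111.000000	0	0	0		
Ppara	6:1 FTOH	PFAS	male	111.000000	6	0	6	Acox1;Angptl4;Apoa5;Cpt2;Cyp4a1;Hmgcs2	
Hnf4a	6:1 FTOH	PFAS	male	111.000000	0	4	4		Cyp7a1;G0s2;Pck1;Tat
Ahr	6:1 FTOH	PFAS	male	111.000000	0	4	4		Aldh1a1;Cyp1a1;Cyp1a2;Nqo1
Nr3c1	6:1 FTOH	PFAS	male	111.000000	0	1	1		Tat
Srebf1	6:1 FTOH	PFAS	male	111.000000	0	2	2		Pck1;Scd
Esr1	6:1 FTOH	PFAS	male	111.000000	0	0	0		
Ppara	6:1 FTOH	PFAS	female	1000.000000	8	0	8	Acadm;Acox1;Angptl4;Apoa1;Apoa5;Cpt2;Cyp4a1;Hmgcs2	
Hnf4a	6:1 FTOH	PFAS	female	1000.000000	6	0	6	Apoa1;Cyp7a1;G0s2;Igfbp1;Pck1;Tat	
Ahr	6:1 FTOH	PFAS	female	1000.000000	0	4	4		Aldh1a1;Cyp1a1;Cyp1a2;Nqo1
Nr3c1	6:1 FTOH	PFAS	female	1000.000000	2	0	2	Igfbp1;Tat	
Srebf1	6:1 FTOH	PFAS	female	1000.000000	1	0	1	Pck1	
Esr1	6:1 FTOH	PFAS	female	1000.000000	0	0	0		
Ppara	6:1 FTOH	PFAS	male	1000.000000	8	0	8	Acadm;Acox1;Angptl4;Apoa1;Apoa5;Cpt2;Cyp4a1;Hmgcs2	
Hnf4a	6:1 FTOH	PFAS	male	1000.000000	1	5	6	Apoa1	Cyp7a1;G0s2;Igfbp1;Pck1;Tat
Ahr	6:1 FTOH	PFAS	male	1000.000000	0	4	4		Aldh1a1;Cyp1a1;Cyp1a2;Nqo1
Nr3c1	6:1 FTOH	PFAS	male	1000.000000	0	2	2		Igfbp1;Tat
Srebf1	6:1 FTOH	PFAS	male	1000.000000	0	2	2		Fads1;Pck1
Esr1	6:1 FTOH	PFAS	male	1000.000000	0	0	0		
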