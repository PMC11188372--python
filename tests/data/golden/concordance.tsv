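chemical	dose_mg_per_kg	sex	gene	weight	log2fc	q	status
2,3-Benzofluorene	1000.000000	female	Scd	1.000000	0.350482	0.622632	not_significant
2,3-Benzofluorene	1000.000000	female	Acox1	1.000000	0.081647	0.898043	not_significant
2,3-Benzofluorene	1000.000000	female	Nqo1	1.000000	1.655726	0.041741	concordant
2,3-Benzofluorene	1000.000000	female	Pck1	-1.000000	1.567618	0.057956	discordant
2,3-Benzofluorene	1000.000000	female	Cyp7a1	-1.000000	1.162459	0.041741	discordant
2,3-Benzofluorene	1000.000000	female	Abcg5	-1.000000	-0.159128	0.847618	not_significant
2,3-Benzofluorene	1000.000000	male	Scd	1.000000	0.234925	0.817449	not_significant
2,3-Benzofluorene	1000.000000	male	Acox1	1.000000	0.176215	0.817449	not_significant
2,3-Benzofluorene	1000.000000	male	Nqo1	1.000000	1.633449	0.008803	concordant
2,3-Benzofluorene	1000.000000	male	Pck1	-1.000000	-1.323319	0.008803	concordant
2,3-Benzofluorene	1000.000000	male	Cyp7a1	-1.000000	-1.150221	0.124658	not_significant
2,3-Benzofluorene	1000.000000	male	Abcg5	-1.000000	0.243503	0.817449	not_significant
6:1 FTOH	1000.000000	female	Scd	1.000000	-0.359991	0.504676	not_significant
6:1 FTOH	1000.000000	female	Acox1	1.000000	1.219888	0.018667	concordant
6:1 FTOH	1000.000000	female	Nqo1	1.000000	-1.478558	0.001883	discordant
6:1 FTOH	1000.000000	female	Pck1	-1.000000	1.861678	0.018496	discordant
6:1 FTOH	1000.000000	female	Cyp7a1	-1.000000	1.305318	0.002595	discordant
6:1 FTOH	1000.000000	female	Abcg5	-1.000000	0.090058	0.854998	not_significant
6:1 FTOH	1000.000000	male	Scd	1.000000	-0.476063	0.137262	not_significant
6:1 FTOH	1000.000000	male	Acox1	1.000000	2.493311	0.002415	concordant
6:1 FTOH	1000.000000	male	Nqo1	1.000000	-2.168941	0.006822	discordant
6:1 FTOH	1000.000000	male	Pck1	-1.000000	-1.999265	0.000922	concordant
6:1 FTOH	1000.000000	male	Cyp7a1	-1.000000	-1.617564	0.006321	concordant
6:1 FTOH	1000.000000	male	Abcg5	-1.000000	0.077678	0.801194	not_significant
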