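gene	pattern	supporting_cells	trend::2,3-Benzofluorene::female	trend::2,3-Benzofluorene::male	trend::6:1 FTOH::female	trend::6:1 FTOH::male
Abcc3	none	2,3-Benzofluorene/male	none	down	none	none
Abcg5	none		none	none	none	none
Acaca	none		none	none	none	none
Acadm	none	6:1 FTOH/female;6:1 FTOH/male	none	none	none	up
Acox1	none	6:1 FTOH/female;6:1 FTOH/male	none	none	none	up
Ahr	none	2,3-Benzofluorene/male	none	down	none	none
Aldh1a1	class_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	none	up	down	down
Angptl4	none	6:1 FTOH/female;6:1 FTOH/male	none	none	up	up
Apoa1	none	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	down	up	up
Apoa5	none	6:1 FTOH/female;6:1 FTOH/male	none	none	up	up
BG00001	none		none	none	none	none
BG00002	none	6:1 FTOH/male	none	none	none	up
BG00003	none		none	none	none	none
BG00004	none		none	none	none	none
BG00005	none		none	none	none	none
BG00006	none		none	none	none	none
BG00007	none		none	none	none	none
BG00008	none	6:1 FTOH/female	none	none	down	none
BG00009	none		none	none	none	none
Cdkn1a	none		none	none	none	none
Cpt2	none	6:1 FTOH/female;6:1 FTOH/male	none	none	up	up
Cyp1a1	class_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	up	down	down
Cyp1a2	class_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	up	down	none
Cyp4a1	none	6:1 FTOH/female;6:1 FTOH/male	none	none	up	up
Cyp7a1	sex_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	none	down	none	down
Esr1	none		none	none	none	none
Fads1	none	6:1 FTOH/male	none	none	none	none
G0s2	sex_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	none	none	none
Hmgcs2	none	6:1 FTOH/female;6:1 FTOH/male	none	none	up	up
Hnf4a	none		none	none	none	none
Igfbp1	sex_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	none	down	up	down
Igfbp3	none		none	none	none	none
Myc	none		none	none	none	none
Nqo1	class_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	up	down	down
Nr3c1	none		none	none	none	none
Pck1	sex_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	down	up	down
Ppara	none	6:1 FTOH/female	none	none	none	none
Scd	none		none	none	none	none
Srebf1	none		none	none	none	none
Tat	sex_dependent	2,3-Benzofluorene/female;2,3-Benzofluorene/male;6:1 FTOH/female;6:1 FTOH/male	up	down	up	down
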