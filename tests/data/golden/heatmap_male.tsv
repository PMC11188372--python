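gene	2,3-Benzofluorene|12|male	2,3-Benzofluorene|111|male	2,3-Benzofluorene|1000|male	6:1 FTOH|12|male	6:1 FTOH|111|male	6:1 FTOH|1000|male
Hmgcs2	0.166929	0.517735	0.435687	0.211972	1.073356	1.547704
Acadm	-0.490024	0.031434	-0.064307	0.372484	0.588433	1.865241
Angptl4	0.177392	0.122343	0.345371	0.266901	0.693565	2.324212
Apoa5	0.333204	0.190015	0.310471	0.647182	0.678689	2.042272
Cyp4a1	0.073658	-0.23554	-0.106444	0.344094	1.326502	2.117718
Acox1	0.223967	-0.621716	0.176215	0.700488	1.218161	2.493311
Cpt2	0.246031	-0.341896	0.402234	0.664999	1.046526	2.110778
Aldh1a1	0.106148	0.670825	0.794279	-0.562491	-0.881416	-1.788216
Nqo1	0.074713	0.914798	1.633449	-0.89524	-1.081895	-2.168941
Cyp1a1	0.824685	1.21631	2.071939	-0.060139	-0.909998	-1.747917
Cyp1a2	0.846889	1.103395	1.167338	0.313988	-0.674479	-1.215588
Pck1	-0.163236	-0.677199	-1.323319	-0.435936	-0.681704	-1.999265
Cyp7a1	-0.399854	-0.649532	-1.150221	-0.511031	-1.225662	-1.617564
Tat	-0.095235	-0.953431	-1.427263	-0.412403	-1.039544	-1.331817
G0s2	0.114028	-0.629725	-1.488934	0.174539	-0.901615	-1.51464
Igfbp1	-0.115004	-1.011597	-2.069413	-0.068542	-0.576418	-1.535023
Apoa1	-0.292471	-1.317182	-1.74008	0.209228	0.485367	0.684952
Scd	0.578899	0.376671	0.234925	-0.279162	-0.623861	-0.476063
Abcc3	-0.290871	-0.269396	-0.814556	0.07494	-0.180198	0.364533
Abcg5	0.110804	-0.298466	0.243503	-0.171249	-0.067644	0.077678
Acaca	-0.197597	-0.340502	0.100756	0.091469	0.413253	0.03764
Igfbp3	-0.194511	-0.385552	-0.075428	0.3156	-0.069694	-0.042688
Fads1	-0.291106	0.221431	-0.23689	-0.462105	0.07042	-0.663029
Cdkn1a	-0.498012	0.098953	-0.152159	-0.014302	-0.106509	-0.503264
Myc	-0.588147	-0.364128	0.047379	-0.160591	-0.16423	-0.316988
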