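gene	2,3-Benzofluorene|12|female	2,3-Benzofluorene|111|female	2,3-Benzofluorene|1000|female	6:1 FTOH|12|female	6:1 FTOH|111|female	6:1 FTOH|1000|female
Apoa1	0.249224	0.868809	1.476864	0.499435	1.915407	3.453004
Cyp1a2	0.10241	0.321616	0.775664	-0.263469	-0.625388	-1.317302
Aldh1a1	-0.179636	0.507161	2.082367	-0.233477	-0.187674	-1.279799
Cyp1a1	0.06584	0.50169	1.643472	-0.111433	-0.462671	-1.310121
Nqo1	0.236862	0.571547	1.655726	-0.319987	-0.578708	-1.478558
Scd	0.25499	0.09277	0.350482	0.438466	0.300418	-0.359991
Fads1	0.104945	0.090295	-0.19209	-0.405071	0.30975	-0.183738
Abcg5	-0.357091	-0.486537	-0.159128	0.183689	0.586943	0.090058
Myc	-0.367987	-0.009016	-0.306017	0.135398	0.298448	0.388384
Cdkn1a	0.046128	-0.022567	-0.030767	0.061121	0.176625	0.027654
Igfbp3	0.034514	-0.295978	-0.487106	0.082343	0.337579	0.051431
Abcc3	-0.309464	-0.352391	0.129715	-0.172002	-0.057808	0.397841
Acaca	-0.591253	-0.386113	-0.332462	0.255742	-0.128977	0.202894
Acadm	0.020628	0.013179	0.267289	-0.451958	0.852313	1.847797
Acox1	0.105373	-0.039604	0.081647	-0.287459	0.545277	1.219888
Hmgcs2	0.144756	0.034144	0.090567	0.090012	0.588252	1.724868
Apoa5	-0.072248	-0.018853	-0.219479	0.442424	1.094517	2.117321
Cpt2	-0.401531	0.170391	0.000856	0.351415	0.955434	1.995342
Angptl4	0.570808	0.25613	-0.248157	0.151669	0.977588	1.658468
Cyp4a1	0.393391	0.256996	0.204767	0.240229	1.229668	2.051681
Cyp7a1	-0.202216	0.224035	1.162459	-0.472384	0.222303	1.305318
Igfbp1	-0.103081	0.499405	0.852956	0.249807	0.467787	1.174343
Pck1	0.598234	1.147008	1.567618	0.298392	1.185156	1.861678
G0s2	0.038273	0.445148	1.760183	-0.061658	0.887262	1.419779
Tat	0.302827	0.739674	1.624858	0.380825	0.697215	1.332254
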