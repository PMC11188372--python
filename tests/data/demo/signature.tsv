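gene	weight
Scd	1.0
Acox1	1.0
Nqo1	1.0
Pck1	-1.0
Cyp7a1	-1.0
Abcg5	-1.0
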