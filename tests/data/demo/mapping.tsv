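source_symbol	destination_symbol
PPARA	Ppara
HNF4A	Hnf4a
NR3C1	Nr3c1
SREBF1	Srebf1
CYP4A1	Cyp4a1
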