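mie	n_targets	n_mapped
Ppara	8	8
Hnf4a	6	6
Ahr	4	4
Nr3c1	4	4
Srebf1	4	4
Esr1	3	3
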