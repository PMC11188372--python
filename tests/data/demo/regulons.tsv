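PPARA	ACOX1	Activation	SYN:1
PPARA	CPT2	Activation	SYN:2
PPARA	ACADM	Activation	SYN:3
PPARA	APOA1	Repression	SYN:4
PPARA	APOA5	Repression	SYN:5
PPARA	ANGPTL4	Activation	SYN:6
PPARA	CYP4A1	Activation	SYN:7
PPARA	HMGCS2	Activation	SYN:8
HNF4A	PCK1	Activation	SYN:9
HNF4A	CYP7A1	Activation	SYN:10
HNF4A	APOA1	Activation	SYN:11
HNF4A	G0S2	Unknown	SYN:12
HNF4A	IGFBP1	Activation	SYN:13
HNF4A	TAT	Activation	SYN:14
AHR	CYP1A1	Activation	SYN:15
AHR	CYP1A2	Activation	SYN:16
AHR	NQO1	Activation	SYN:17
AHR	ALDH1A1	Unknown	SYN:18
NR3C1	TAT	Activation	SYN:19
NR3C1	IGFBP1	Repression	SYN:20
NR3C1	MYC	Repression	SYN:21
NR3C1	CDKN1A	Activation	SYN:22
SREBF1	SCD	Activation	SYN:23
SREBF1	PCK1	Unknown	SYN:24
SREBF1	FADS1	Activation	SYN:25
SREBF1	ACACA	Activation	SYN:26
ESR1	ABCC3	Activation	SYN:27
ESR1	ABCG5	Repression	SYN:28
ESR1	IGFBP3	Activation	SYN:29
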