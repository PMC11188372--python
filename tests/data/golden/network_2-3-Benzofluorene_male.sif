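Ppara	regulates	Acox1
Ppara	regulates	Cpt2
Ppara	regulates	Acadm
Ppara	regulates	Apoa1
Ppara	regulates	Apoa5
Ppara	regulates	Angptl4
Ppara	regulates	Cyp4a1
Ppara	regulates	Hmgcs2
Hnf4a	regulates	Pck1
Hnf4a	regulates	Cyp7a1
Hnf4a	regulates	Apoa1
Hnf4a	regulates	G0s2
Hnf4a	regulates	Igfbp1
Hnf4a	regulates	Tat
Ahr	regulates	Cyp1a1
Ahr	regulates	Cyp1a2
Ahr	regulates	Nqo1
Ahr	regulates	Aldh1a1
Nr3c1	regulates	Tat
Nr3c1	regulates	Igfbp1
Nr3c1	regulates	Myc
Nr3c1	regulates	Cdkn1a
Srebf1	regulates	Scd
Srebf1	regulates	Pck1
Srebf1	regulates	Fads1
Srebf1	regulates	Acaca
Esr1	regulates	Abcc3
Esr1	regulates	Abcg5
Esr1	regulates	Igfbp3
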