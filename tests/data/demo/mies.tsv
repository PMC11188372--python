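name	sources
Ppara	target_prediction,literature_review
Hnf4a	aop_database
Ahr	target_prediction,aop_database
Nr3c1	literature_review
Srebf1	literature_review
Esr1	target_prediction
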