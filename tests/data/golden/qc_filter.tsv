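sample_id	qc_pass	failed_rules
s0001	True	
s0002	True	
s0003	True	
s0004	True	
s0005	True	
s0006	True	
s0007	True	
s0008	True	
s0009	True	
s0010	True	
s0011	True	
s0012	True	
s0013	True	
s0014	True	
s0015	True	
s0016	True	
s0017	True	
s0018	True	
s0019	True	
s0020	True	
s0021	True	
s0022	True	
s0023	True	
s0024	True	
s0025	True	
s0026	True	
s0027	True	
s0028	True	
s0029	True	
s0030	True	
s0031	True	
s0032	True	
s0033	True	
s0034	True	
s0035	True	
s0036	True	
s0037	True	
s0038	True	
s0039	True	
s0040	True	
s0041	True	
s0042	True	
s0043	True	
s0044	True	
s0045	True	
s0046	True	
s0047	True	
s0048	True	
s0049	True	
s0050	True	
s0051	True	
s0052	True	
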