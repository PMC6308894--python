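seq_id	primer	m3	m5
SYN0001	Sauron-S878	0	1
SYN0001	jgHCO2198	0	0
SYN0002	Sauron-S878	0	0
SYN0002	jgHCO2198	0	0
SYN0003	Sauron-S878	0	1
SYN0003	jgHCO2198	0	0
SYN0004	Sauron-S878	0	0
SYN0004	jgHCO2198	0	0
SYN0005	Sauron-S878	0	0
SYN0005	jgHCO2198	0	0
SYN0006	Sauron-S878	0	0
SYN0006	jgHCO2198	0	0
SYN0007	Sauron-S878	0	0
SYN0007	jgHCO2198	0	0
SYN0008	Sauron-S878	0	0
SYN0008	jgHCO2198	0	0
SYN0009	Sauron-S878	0	0
SYN0009	jgHCO2198	0	0
SYN0010	Sauron-S878	0	0
SYN0010	jgHCO2198	0	0
SYN0011	Sauron-S878	0	0
SYN0011	jgHCO2198	0	0
SYN0012	Sauron-S878	0	0
SYN0012	jgHCO2198	0	0
SYN0013	Sauron-S878	0	1
SYN0013	jgHCO2198	0	0
SYN0014	Sauron-S878	0	0
SYN0014	jgHCO2198	0	0
SYN0015	Sauron-S878	0	0
SYN0015	jgHCO2198	0	0
SYN0016	Sauron-S878	0	0
SYN0016	jgHCO2198	0	0
SYN0017	Sauron-S878	0	0
SYN0017	jgHCO2198	0	0
SYN0018	Sauron-S878	0	0
SYN0018	jgHCO2198	0	0
SYN0019	Sauron-S878	0	0
SYN0019	jgHCO2198	0	0
SYN0020	Sauron-S878	0	0
SYN0020	jgHCO2198	0	0
SYN0021	Sauron-S878	0	0
SYN0021	jgHCO2198	0	0
SYN0022	Sauron-S878	0	0
SYN0022	jgHCO2198	0	0
SYN0023	Sauron-S878	0	0
SYN0023	jgHCO2198	0	0
SYN0024	Sauron-S878	1	0
SYN0024	jgHCO2198	0	0
SYN0025	Sauron-S878	1	0
SYN0025	jgHCO2198	0	0
SYN0026	Sauron-S878	1	0
SYN0026	jgHCO2198	0	0
SYN0027	Sauron-S878	0	0
SYN0027	jgHCO2198	0	0
SYN0028	Sauron-S878	0	0
SYN0028	jgHCO2198	0	0
SYN0029	Sauron-S878	1	0
SYN0029	jgHCO2198	0	0
SYN0030	Sauron-S878	0	0
SYN0030	jgHCO2198	0	0
SYN0031	Sauron-S878	0	0
SYN0031	jgHCO2198	0	0
SYN0032	Sauron-S878	0	0
SYN0032	jgHCO2198	0	2
SYN0033	Sauron-S878	0	0
SYN0033	jgHCO2198	0	0
SYN0034	Sauron-S878	0	0
SYN0034	jgHCO2198	0	2
SYN0035	Sauron-S878	0	0
SYN0035	jgHCO2198	0	2
SYN0036	Sauron-S878	0	0
SYN0036	jgHCO2198	0	0
SYN0037	Sauron-S878	0	0
SYN0037	jgHCO2198	0	2
SYN0038	Sauron-S878	0	0
SYN0038	jgHCO2198	0	0
SYN0039	Sauron-S878	0	0
SYN0039	jgHCO2198	0	0
SYN0040	Sauron-S878	0	0
SYN0040	jgHCO2198	0	0
SYN0041	Sauron-S878	0	0
SYN0041	jgHCO2198	0	2
SYN0042	Sauron-S878	0	0
SYN0042	jgHCO2198	0	0
SYN0043	Sauron-S878	0	0
SYN0043	jgHCO2198	0	0
SYN0044	Sauron-S878	0	0
SYN0044	jgHCO2198	0	0
SYN0045	Sauron-S878	0	0
SYN0045	jgHCO2198	0	2
SYN0046	Sauron-S878	0	0
SYN0046	jgHCO2198	0	0
SYN0047	Sauron-S878	0	0
SYN0047	jgHCO2198	0	0
SYN0048	Sauron-S878	0	0
SYN0048	jgHCO2198	0	0
SYN0049	Sauron-S878	0	0
SYN0049	jgHCO2198	0	0
SYN0050	Sauron-S878	0	0
SYN0050	jgHCO2198	0	0
SYN0051	Sauron-S878	0	0
SYN0051	jgHCO2198	0	0
SYN0052	Sauron-S878	0	0
SYN0052	jgHCO2198	0	0
SYN0053	Sauron-S878	0	0
SYN0053	jgHCO2198	0	0
SYN0054	Sauron-S878	0	0
SYN0054	jgHCO2198	0	0
SYN0055	Sauron-S878	0	0
SYN0055	jgHCO2198	0	0
SYN0056	Sauron-S878	0	0
SYN0056	jgHCO2198	0	0
SYN0057	Sauron-S878	0	0
SYN0057	jgHCO2198	0	0
SYN0058	Sauron-S878	0	0
SYN0058	jgHCO2198	0	0
SYN0059	Sauron-S878	0	0
SYN0059	jgHCO2198	0	0
SYN0060	Sauron-S878	0	0
SYN0060	jgHCO2198	0	0
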