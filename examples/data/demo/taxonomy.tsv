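seq_id	species	order	class
SYN0001	Genus01 species01	Order01	Insecta
SYN0002	Genus01 species02	Order01	Insecta
SYN0003	Genus01 species03	Order01	Insecta
SYN0004	Genus01 species04	Order01	Insecta
SYN0005	Genus01 species05	Order01	Insecta
SYN0006	Genus01 species06	Order01	Insecta
SYN0007	Genus01 species07	Order01	Insecta
SYN0008	Genus01 species08	Order01	Insecta
SYN0009	Genus01 species09	Order01	Insecta
SYN0010	Genus01 species10	Order01	Insecta
SYN0011	Genus01 species11	Order01	Insecta
SYN0012	Genus01 species12	Order01	Insecta
SYN0013	Genus01 species13	Order01	Insecta
SYN0014	Genus01 species14	Order01	Insecta
SYN0015	Genus01 species15	Order01	Insecta
SYN0016	Genus02 species01	Order02	Arachnida
SYN0017	Genus02 species02	Order02	Arachnida
SYN0018	Genus02 species03	Order02	Arachnida
SYN0019	Genus02 species04	Order02	Arachnida
SYN0020	Genus02 species05	Order02	Arachnida
SYN0021	Genus02 species06	Order02	Arachnida
SYN0022	Genus02 species07	Order02	Arachnida
SYN0023	Genus02 species08	Order02	Arachnida
SYN0024	Genus02 species09	Order02	Arachnida
SYN0025	Genus02 species10	Order02	Arachnida
SYN0026	Genus02 species11	Order02	Arachnida
SYN0027	Genus02 species12	Order02	Arachnida
SYN0028	Genus02 species13	Order02	Arachnida
SYN0029	Genus02 species14	Order02	Arachnida
SYN0030	Genus02 species15	Order02	Arachnida
SYN0031	Genus03 species01	Order03	Mammalia
SYN0032	Genus03 species02	Order03	Mammalia
SYN0033	Genus03 species03	Order03	Mammalia
SYN0034	Genus03 species04	Order03	Mammalia
SYN0035	Genus03 species05	Order03	Mammalia
SYN0036	Genus03 species06	Order03	Mammalia
SYN0037	Genus03 species07	Order03	Mammalia
SYN0038	Genus03 species08	Order03	Mammalia
SYN0039	Genus03 species09	Order03	Mammalia
SYN0040	Genus03 species10	Order03	Mammalia
SYN0041	Genus03 species11	Order03	Mammalia
SYN0042	Genus03 species12	Order03	Mammalia
SYN0043	Genus03 species13	Order03	Mammalia
SYN0044	Genus03 species14	Order03	Mammalia
SYN0045	Genus03 species15	Order03	Mammalia
SYN0046	Genus04 species01	Order04	Actinopterygii
SYN0047	Genus04 species02	Order04	Actinopterygii
SYN0048	Genus04 species03	Order04	Actinopterygii
SYN0049	Genus04 species04	Order04	Actinopterygii
SYN0050	Genus04 species05	Order04	Actinopterygii
SYN0051	Genus04 species06	Order04	Actinopterygii
SYN0052	Genus04 species07	Order04	Actinopterygii
SYN0053	Genus04 species08	Order04	Actinopterygii
SYN0054	Genus04 species09	Order04	Actinopterygii
SYN0055	Genus04 species10	Order04	Actinopterygii
SYN0056	Genus04 species11	Order04	Actinopterygii
SYN0057	Genus04 species12	Order04	Actinopterygii
SYN0058	Genus04 species13	Order04	Actinopterygii
SYN0059	Genus04 species14	Order04	Actinopterygii
SYN0060	Genus04 species15	Order04	Actinopterygii
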