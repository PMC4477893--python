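site_id	maf	carriers	panel_size
rs75994611	0.0115	4	52
rs3794942	0.0744	4	52
rs200158544	?	1	52
novel_A898C	?	1	52
rs115368653	0.0078	1	52
rs77148611	0.0096	2	52
rs3794941	0.2020	16	52
rs17817969	0.079	12	52
rs191767705	0.0032	1	52
rs77006793	0.0032	1	52
rs7227263	0.079	11	52
rs7227391	0.0794	12	52
rs139800364	0.0014	1	52
rs374273356	?	1	52
rs201078153	?	1	52
rs948615	0.2025	10	52
rs73971116	0.0023	1	52
rs368982407	?	1	52
rs12327359	0.4096	35	52
rs114095914	0.0078	1	52
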