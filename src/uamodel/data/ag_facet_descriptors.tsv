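facet	dH_imm_water	dH_imm_water_err	dH_imm_octanol	dH_imm_octanol_err	logP_NM_printed
100	-276.70	1.0	-287.0	3.0	6.04
110	-206.7	0.5	-289.0	5.0	14.49
111	-204.6	0.5	-308.0	5.0	18.13
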