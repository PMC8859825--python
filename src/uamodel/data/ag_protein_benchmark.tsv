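pdb_id	total_charge_e	r_np_nm	zeta_mV	dG_ads_kj_mol	E_ads_A_kj_mol	E_ads_B_kj_mol	experimental_rank
1BLF	13	18.0	-28.1	-81.59	-34.47	-275.63	1
1W0Q	5	40.0	-6.0	-72.85	-27.61	-204.78	2
9PAP	9	40.0	-6.0	-59.76	-37.40	-213.71	3
3V03	-32	40.0	-6.0	-39.49	-30.89	-175.01	4
1AKI	8	40.0	-6.0	-28.71	-32.33	-169.79	5
1AO6	-30	43.0	-6.0	-22.14	-27.87	-154.70	6
1FSX	2	10.0	-12.5	-19.10	-23.54	-111.46	7
1GZX	2	15.0	-15.5	-14.43	-24.54	-112.36	8
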