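mirna	cardiac_NCC	non_NCC	log2fc_printed
miR-363-3p	5.819	N.D.	N/A
miR-466f-3p	4.940	N.D.	N/A
miR-542-5p	4.983	N.D.	N/A
miR-125b-1-3p	5.203	N.D.	N/A
miR-214-5p	7.908	6.294	1.614
miR-199a-5p	9.437	7.979	1.459
miR-20b-5p	9.805	8.417	1.388
miR-500-3p	6.367	5.160	1.207
miR-199b-3p	9.150	8.032	1.118
miR-23b-3p	8.358	9.421	-1.062
miR-127-3p	8.636	9.778	-1.142
miR-329-3p	4.746	5.950	-1.204
miR-708-5p	5.460	6.693	-1.233
miR-126a-3p	6.073	7.600	-1.526
miR-31-5p	4.626	6.576	-1.951
miR-182-5p	5.056	10.076	-5.020
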