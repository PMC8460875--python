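mirna	log2_signal	sequence	cluster
miR-709	13.275	GGAGGCAGAGGCAGGAGGA	Not in cluster
miR-17-5p	12.214	CAAAGUGCUUACAGUGCAGGUAG	miR-17-92 cluster
miR-20a-5p	11.196	UAAAGUGCUUAUAGUGCAGGUAG	miR-17-92 cluster
miR-92a-3p	10.689	UAUUGCACUUGUCCCGGCCUG	miR-17-92 cluster
miR-690	10.651	AAAGGCUAGGCUCACAACCAAA	Not in cluster
miR-106a-5p	10.517	CAAAGUGCUAACAGUGCAGGUAG	miR-106a-363 cluster
miR-93-5p	10.374	CAAAGUGCUGUUCGUGCAGGUAG	miR-106b-25 cluster
miR-103-3p	10.313	AGCAGCAUUGUACAGGGCUAUGA	Not in cluster
miR-214-3p	10.203	ACAGCAGGCACAGACAGGCAGU	miR-199a-214 cluster
miR-18a-5p	10.201	UAAGGUGCAUCUAGUGCAGAUAG	miR-17-92 cluster
miR-99b-5p	10.120	CACCCGUAGAACCGACCUUGCG	miR-99b-125a cluster
miR-16-5p	9.909	UAGCAGCACGUAAAUAUUGGCG	miR-15-16 cluster
miR-20b-5p	9.805	CAAAGUGCUCAUAGUGCAGGUAG	miR-106a-363 cluster
miR-107-3p	9.764	AGCAGCAUUGUACAGGGCUAUCA	Not in cluster
miR-181a-5p	9.763	AACAUUCAACGCUGUCGGUGAGU	miR-181a/b cluster
miR-181b-5p	9.622	AACAUUCAUUGCUGUCGGUGGGU	miR-181a/b cluster
miR-130b-3p	9.573	CAGUGCAAUGAUGAAAGGGCAU	miR-130b-301b cluster
miR-19b-3p	9.526	UGUGCAAAUCCAUGCAAAACUGA	miR-17-92 cluster
miR-26a-5p	9.457	UUCAAGUAAUCCAGGAUAGGCU	Not in cluster
miR-199a-5p	9.437	CCCAGUGUUCAGACUACCUGUUC	miR-199a-214 cluster
miR-125a-5p	9.361	UCCCUGAGACCCUUUAACCUGUGA	miR-99b-125a cluster
miR-199a-3p	9.167	ACAGUAGUCUGCACAUUGGUUA	miR-199a-214 cluster
miR-125b-5p	9.158	UCCCUGAGACCCUAACUUGUGA	miR-99a-125b cluster
miR-199b-3p	9.150	ACAGUAGUCUGCACAUUGGUUA	miR-199b-3154 cluster
miR-130a-3p	9.132	CAGUGCAAUGUUAAAAGGGCAU	Not in cluster
miR-145a-5p	9.010	GUCCAGUUUUCCCAGGAAUCCCU	miR-143-145 cluster
let-7e-5p	8.949	UGAGGUAGGAGGUUGUAUAGUU	miR-99b-125a cluster
miR-106b-5p	8.858	UAAAGUGCUGACAGUGCAGAU	miR-106b-25 cluster
miR-541-5p	8.856	AAGGGAUUCUGAUGUUGGUCACACU	Mirg cluster
miR-1195	8.752	UGAGUUCGAGGCCAGCCUGCUCA	Not in cluster
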