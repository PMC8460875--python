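mirna	log2_signal	sequence	cluster
miR-709	13.38065	GGAGGCAGAGGCAGGAGGA	Not in cluster
miR-17-5p	12.06354	CAAAGUGCUUACAGUGCAGGUAG	miR-17-92 cluster
miR-690	11.37133	AAAGGCUAGGCUCACAACCAAA	Not in cluster
miR-99b-5p	10.85722	CACCCGUAGAACCGACCUUGCG	miR-99b-125a cluster
miR-20a-5p	10.73113	UAAAGUGCUUAUAGUGCAGGUAG	miR-17-92 cluster
miR-92a-3p	10.66891	UAUUGCACUUGUCCCGGCCUG	miR-17-92 cluster
miR-93-5p	10.25503	CAAAGUGCUGUUCGUGCAGGUAG	miR-106b-25 cluster
miR-103-3p	10.16812	AGCAGCAUUGUACAGGGCUAUGA	Not in cluster
miR-182-5p	10.07562	UUUGGCAAUGGUAGAACUCACACCG	miR-182-183 cluster
miR-16-5p	10.03377	UAGCAGCACGUAAAUAUUGGCG	miR-15-16 cluster
miR-106a-5p	9.949529	CAAAGUGCUAACAGUGCAGGUAG	miR-106a-363 cluster
miR-125a-5p	9.923689	UCCCUGAGACCCUUUAACCUGUGA	miR-99b-125a cluster
miR-107-3p	9.916354	AGCAGCAUUGUACAGGGCUAUCA	Not in cluster
miR-26a-5p	9.854673	UUCAAGUAAUCCAGGAUAGGCU	Not in cluster
miR-127-3p	9.778021	UCGGAUCCGUCUGAGCUUGGCU	miR-136-431 cluster
miR-145a-5p	9.766548	GUCCAGUUUUCCCAGGAAUCCCU	miR-143-145 cluster
miR-541-5p	9.682595	AAGGGAUUCUGAUGUUGGUCACACU	Mirg cluster
miR-214-3p	9.590926	ACAGCAGGCACAGACAGGCAGU	miR-199a-214 cluster
miR-181b-5p	9.429933	AACAUUCAUUGCUGUCGGUGGGU	miR-181a/b cluster
miR-130b-3p	9.42875	CAGUGCAAUGAUGAAAGGGCAU	miR-130b-301b cluster
miR-23b-3p	9.420783	AUCACAUUGCCAGGGAUUACC	miR-23b-24 cluster
miR-181a-5p	9.411454	AACAUUCAACGCUGUCGGUGAGU	miR-181a/b cluster
miR-125b-5p	9.3161	UCCCUGAGACCCUAACUUGUGA	miR-99a-125b cluster
miR-24-3p	9.314174	UGGCUCAGUUCAGCAGGAACAG	miR-23b-24 cluster
miR-18a-5p	9.269115	UAAGGUGCAUCUAGUGCAGAUAG	miR-17-92 cluster
let-7e-5p	9.152258	UGAGGUAGGAGGUUGUAUAGUU	miR-99b-125a cluster
miR-762	9.083022	GGGGCUGGGGCCGGGACAGAGC	Not in cluster
miR-1195	9.081083	UGAGUUCGAGGCCAGCCUGCUCA	Not in cluster
miR-130a-3p	9.068733	CAGUGCAAUGUUAAAAGGGCAU	Not in cluster
miR-351-5p	9.066365	UCCCUGAGGAGCCCUUUGAGCCUG	miR-322-351 cluster
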