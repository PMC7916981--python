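name	sequence
hsa-miR-199a-3p	ACAGUAGUCUGCACAUUGGUUA
hsa-miR-335-5p	UCAAGAGCAAUAACGAAAAAUGU
hsa-miR-425-5p	AAUGACACGAUCACUCCCGUUGA
hsa-miR-1225-3p	UGAGCCCCUGUGCCGCCCCCAG
hsa-miR-1233-3p	UGAGCCCUGUCCUCCCGCAG
hsa-miR-1274b	UCCCUGUUCGGGCGCCA
hsa-miR-1303	UUUAGAGACGGGGUCUUGCUCU
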