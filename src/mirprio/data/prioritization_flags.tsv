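gene	mirna	two_dbs	energy	rna22	direct_validation	dse_present	gene_assoc	crc_assoc
L1TD1	hsa-miR-1303	+	+	fail	-	+	+	+
SLITRK6	hsa-miR-199a-3p	+	-	pass	-	+	+	+
SLITRK6	hsa-miR-425-5p	-	+	fail	+	+	+	+
ST6GALNAC1	hsa-miR-335-5p	+	+	fail	-	+	+	+
TCEA3	hsa-miR-335-5p	+	+	fail	-	+	+	+
TCEA3	hsa-miR-1225-3p	+	+	fail	-	+	+	+
TCEA3	hsa-miR-1233-3p	+	+	near_miss	-	+	+	+
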