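knockout	subsystem	n_down	n_up	printed_p
PGM1	Amino Acid Metabolism	61	160	<0.00001
PGM1	Carbohydrate Metabolism	35	55	0.03501
PGM1	Cofactor and Vitamin Metabolism	20	75	<0.00001
PGM1	Energy Metabolism	12	34	0.00118
PGM1	Glycan Metabolism	60	283	<0.00001
PGM1	Lipid Metabolism	109	243	<0.00001
PGM1	Nucleotide Metabolism	64	103	0.00255
PGM1	Other Amino Acids Metabolism	6	19	0.00932
PGM1	Secondary Metabolites Metabolism	0	0	1.00000
PGM1	Transporters	368	437	0.01502
FUT9	Amino Acid Metabolism	85	133	0.00115
FUT9	Carbohydrate Metabolism	48	48	1.00000
FUT9	Cofactor and Vitamin Metabolism	53	45	0.41900
FUT9	Energy Metabolism	19	27	0.23820
FUT9	Glycan Metabolism	118	229	<0.00001
FUT9	Lipid Metabolism	165	189	0.20210
FUT9	Nucleotide Metabolism	80	91	0.40020
FUT9	Other Amino Acids Metabolism	11	14	0.54850
FUT9	Secondary Metabolites Metabolism	0	0	1.00000
FUT9	Transporters	397	422	0.38240
SORD	Amino Acid Metabolism	122	98	0.10560
SORD	Carbohydrate Metabolism	40	55	0.12380
SORD	Cofactor and Vitamin Metabolism	60	37	0.01953
SORD	Energy Metabolism	27	19	0.23820
SORD	Glycan Metabolism	166	182	0.39110
SORD	Lipid Metabolism	196	162	0.07234
SORD	Nucleotide Metabolism	87	90	0.82160
SORD	Other Amino Acids Metabolism	12	13	0.84150
SORD	Secondary Metabolites Metabolism	0	0	1.00000
SORD	Transporters	393	443	0.08376
DHCR7	Amino Acid Metabolism	68	152	<0.00001
DHCR7	Carbohydrate Metabolism	22	75	<0.00001
DHCR7	Cofactor and Vitamin Metabolism	25	71	<0.00001
DHCR7	Energy Metabolism	13	32	0.00462
DHCR7	Glycan Metabolism	49	294	<0.00001
DHCR7	Lipid Metabolism	128	225	<0.00001
DHCR7	Nucleotide Metabolism	45	122	<0.00001
DHCR7	Other Amino Acids Metabolism	7	18	0.02781
DHCR7	Secondary Metabolites Metabolism	0	0	1.00000
DHCR7	Transporters	337	479	<0.00001
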