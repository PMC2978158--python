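gene	subgroup	lethal	comment
EBP	Cholesterol Metabolism	yes	X-linked; homozygous males non-viable (prenatal lethality)
DHCR7	Cholesterol Metabolism	yes	Prenatal lethality of homozygotes
DHCR24	Cholesterol Metabolism	yes	Prenatal lethality of homozygotes
FDFT1	Cholesterol Metabolism	yes	Prenatal lethality of homozygotes
HSD17B4	Cholesterol Metabolism	yes	Pre/peri/postnatal lethality of homozygotes
NSDHL	Cholesterol Metabolism	yes	X-linked; males and homozygous females non-viable
SC5DL	Cholesterol Metabolism	yes	Perinatal lethality of homozygotes
SPTLC1	Sphingolipid Metabolism	yes	Embryonic lethality of homozygotes
DHFR	Folate Metabolism	yes	Embryonic lethality of homozygotes
PISD	Glycerophospholipid Metabolism	yes	Embryonic lethality of homozygotes
PHGDH	Glycine, Serine, and Threonine Metabolism	yes	Embryonic lethality of homozygotes
HMGCR	Cholesterol Metabolism	yes	Embryonic lethality of homozygotes
CBS	Methionine Metabolism	yes	Homozygotes die within 5 weeks after birth
SPTLC2	Sphingolipid Metabolism	yes	Embryonic lethality of homozygotes
PAH	Tyr, Phe, Trp Biosynthesis	no	Homozygous disruption viable
TM7SF2	Cholesterol Metabolism	no	Homozygotes for mutations viable
Gpam	Triacylglycerol Synthesis	no	Homozygotes viable
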