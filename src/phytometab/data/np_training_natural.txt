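# Natural-product training structures for the NP-likeness model.
# One record per line: SMILES<TAB>name. Hand-assembled set of plant
# secondary metabolites (terpenoids, phenylpropanoids, flavonoids,
# coumarins, alkaloids, sugars, amino acids).
CC1=CCC(CC1)C(=C)C	limonene
CC1=CCC2CC1C2(C)C	alpha-pinene
CC1CCC(C(C)C)C(O)C1	menthol
CC1(C)C2CCC1(C)C(=O)C2	camphor
CC(=CCCC(=CCO)C)C	geraniol
CC(=CCCC(C)(C=C)O)C	linalool
CC1=CC(=O)CC(C)(C)C1	isophorone
CC(C)C1=CC=C(C)C=C1O	carvacrol
CC(C)C1=CC=C(C)C=C1	p-cymene
CC1=CCC(CC1=O)C(C)=C	carvone
CC(=CCCC(=CCC=C(C)C=C)C)C	beta-farnesene
CC(=CCCC(=CC=O)C)C	citral
CC12CCC(CC1=CCC2=O)C(C)C	nootkatone-core
CC1CCC2(CCC3(C)C(CCC4C3CCC3(C)C(C(C)C)CCC43)C2C1)C	sterane-scaffold
CC(C)=CCCC(C)=CCCC(C)=CCO	farnesol
CC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CCO	geranylgeraniol
OC1CC2CCC1(C)C2(C)C	borneol
CC1=CC2CC(C)(C)C2CC1=O	filifolone-like
c1ccc2c(c1)oc(=O)cc2	coumarin
Oc1ccc2ccc(=O)oc2c1	umbelliferone
COc1cc2ccc(=O)oc2cc1O	scopoletin
Oc1cc2oc(=O)ccc2cc1O	esculetin
c1cc2cc3ccc(=O)oc3cc2o1	psoralen
COc1cc2occ(-c3ccc(O)cc3)c(=O)c2cc1	methoxy-isoflavone
Oc1ccc(cc1)/C=C/C(=O)O	p-coumaric-acid
COc1cc(/C=C/C(=O)O)ccc1O	ferulic-acid
Oc1ccc(/C=C/C(=O)O)cc1O	caffeic-acid
Oc1cc(O)cc(O)c1	phloroglucinol
OC(=O)c1cc(O)c(O)c(O)c1	gallic-acid
COc1cc(C(=O)O)ccc1O	vanillic-acid
OC(=O)/C=C/c1ccccc1	cinnamic-acid
Oc1ccc(C=O)cc1	p-hydroxybenzaldehyde
COc1cc(C=O)ccc1O	vanillin
Oc1ccc(cc1)-c1cc(=O)c2c(O)cc(O)cc2o1	apigenin
Oc1cc(O)c2c(c1)oc(-c1ccccc1)cc2=O	chrysin
Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O	quercetin
Oc1cc(O)c2c(c1)oc(-c1ccc(O)cc1)c(O)c2=O	kaempferol
Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2	catechin
Oc1ccc(cc1)C1CC(=O)c2c(O)cc(O)cc2O1	naringenin
COc1ccc(cc1O)-c1cc(=O)c2c(O)cc(O)cc2o1	hesperetin-like
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	resveratrol
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
CN1CCCC1c1cccnc1	nicotine
OC(=O)c1cccnc1	nicotinic-acid
c1ccc2c(c1)[nH]c1ccccc12	carbazole
c1ccc2[nH]ccc2c1	indole
OC(=O)C(N)Cc1c[nH]c2ccccc12	tryptophan
OC(=O)/C=C/c1c[nH]c2ccccc12	indoleacrylic-acid
COc1ccc2[nH]cc(CCN)c2c1	methoxytryptamine
NCCc1c[nH]c2ccccc12	tryptamine
COc1ccc2c(c1)nccc2C(O)C1CC2CCN1CC2C=C	quinine-core
CN1CCc2cccc3c2C1Cc1ccc(O)c(O)c1-3	aporphine-core
COc1cc2c(cc1OC)C(=O)C(CC1CCN(C)CC1)C2	lobeline-like
O=C(/C=C/C=C/c1ccc2OCOc2c1)N1CCCCC1	piperine
NCCc1ccc(O)c(O)c1	dopamine
NC(Cc1ccc(O)cc1)C(=O)O	tyrosine
NC(Cc1ccccc1)C(=O)O	phenylalanine
NC(CC(=O)N)C(=O)O	asparagine
OC(=O)C1CCCN1	proline
NC(CO)C(=O)O	serine
NC(CCC(=O)O)C(=O)O	glutamate
OCC1OC(O)C(O)C(O)C1O	glucose
OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O	sucrose
OCC(O)C(O)C(O)C(O)CO	sorbitol
CC(=O)OC1CC2CCC3C(CCC4(C)C3CCC4C(C)CCCC(C)C)C2(C)CC1	sterol-ester-like
CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C	cholesterol
CCCCCCCC/C=C\CCCCCCCC(=O)O	oleic-acid
CCCCCCCCCCCCCCCC(=O)O	palmitic-acid
CCCCC/C=C\C/C=C\CCCCCCCC(=O)O	linoleic-acid
OCC(O)CO	glycerol
CC(=O)OC1CCC2(C)C(=CCC3C2CCC2(C)C3CCC2C(C)=O)C1	pregnane-like
OC(=O)CC(O)(CC(=O)O)C(=O)O	citric-acid
OC(=O)C(O)C(O)C(=O)O	tartaric-acid
CC1OC(O)C(O)C(O)C1O	rhamnose-core
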