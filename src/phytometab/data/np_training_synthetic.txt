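# Synthetic/medicinal-chemistry training structures for the NP-likeness
# model: drug-like and agrochemical scaffolds rich in halogens, sulfonamides,
# nitro groups, trifluoromethyls and fused N-heteroaromatics that are rare in
# plant natural products. One record per line: SMILES<TAB>name.
CC(C)Cc1ccc(cc1)C(C)C(=O)O	ibuprofen
CC(=O)Oc1ccccc1C(=O)O	aspirin
Cc1onc(c1)-c1ccccc1S(N)(=O)=O	sulfonamide-isoxazole
NS(=O)(=O)c1ccc(N)cc1	sulfanilamide
Cc1noc(C)c1S(=O)(=O)Nc1ccccc1	sulfonanilide
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21	diazepam
FC(F)(F)c1ccc(cc1)C(CCNC)Oc1ccccc1	fluoxetine
CCNc1nc(Cl)nc(NC(C)C)n1	atrazine
OC(=O)CNCP(=O)(O)O	glyphosate
Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl	DDT
NC(=O)N1c2ccccc2C=Cc2ccccc21	carbamazepine
CC(C)NCC(O)COc1ccc(CCOC)cc1	metoprolol
O=[N+]([O-])c1ccc(Cl)cc1	chloronitrobenzene
O=[N+]([O-])c1ccccc1C(F)(F)F	nitro-trifluorotoluene
Clc1ccccc1Cl	dichlorobenzene
Clc1cc(Cl)c(Cl)cc1Cl	tetrachlorobenzene
FC(F)(F)c1cccc(c1)N	trifluoromethylaniline
CCOC(=O)c1ccccc1C(=O)OCC	diethyl-phthalate
CCCCOC(=O)c1ccccc1C(=O)OCCCC	dibutyl-phthalate
COC(=O)c1ccc(O)cc1	methylparaben
CC(C)(c1ccc(O)cc1)c1ccc(O)cc1	bisphenol-A
Cc1ccc(cc1[N+](=O)[O-])[N+](=O)[O-]	dinitrotoluene
Clc1ccc(cc1)S(=O)(=O)Nc1ncccn1	sulfonyl-pyrimidine
CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1	diuron
CCN(CC)C(=O)C(C)Oc1cccc2ccccc12	napropamide
CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]	parathion
COP(=O)(OC)OC=C(Cl)Cl	dichlorvos
Clc1ccc(CN2CCN(CC2)c2ccc(Cl)cc2)cc1	piperazine-dichloride
Fc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1	haloperidol
CN1CCN(CC1)C(=O)c1cc2cc(Cl)ccc2[nH]1	chloroindole-amide
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
CCN(CC)CCNC(=O)c1ccc(N)cc1	procainamide
COc1ccc(cc1)S(=O)(=O)N1CCCC1	methoxysulfonyl-pyrrolidine
Fc1ccccc1-c1nc2ccccc2s1	fluorophenyl-benzothiazole
Clc1nc2ccccc2s1	chlorobenzothiazole
c1ccc(nc1)-c1ccccn1	bipyridine
Brc1ccc(cc1)C(=O)N1CCOCC1	bromobenzoyl-morpholine
FC(F)(F)Oc1ccccc1	trifluoromethoxybenzene
CC(C)(C)c1ccc(O)cc1	tert-butylphenol
N#Cc1ccc(cc1)C#N	terephthalonitrile
O=S(=O)(c1ccccc1)c1ccccc1	diphenylsulfone
CN(C)c1ccc(cc1)N=Nc1ccccc1	dimethylaminoazobenzene
CCOc1ccc(NC(C)=O)cc1	phenacetin
Clc1ccccc1-c1nnc(o1)-c1ccccc1Cl	dichloro-oxadiazole
CCN1CCN(CC1)c1nc2ccccc2n1C	methylbenzimidazole-piperazine
O=C1N(CCCCN2CCN(CC2)c2cccc(Cl)c2Cl)C(=O)c2ccccc21	phthalimide-piperazine
CC1(C)OC(=O)N(c2ccc(Cl)cc2)C1=O	oxazolidinedione
CCOC(=O)N1CCN(CC1)C(=O)c1ccc(F)cc1	fluorobenzoyl-carbamate
Fc1ccc(cc1)S(=O)(=O)N1CCCCC1	fluorosulfonyl-piperidine
CSc1ccc(cc1)C(=O)c1ccccc1	methylthio-benzophenone
O=C(Nc1ccc(Cl)cc1)Nc1ccccc1	chlorocarbanilide
CC(C)Oc1cc(NC(=O)N(C)C)ccc1Cl	chlorophenyl-urea
Cn1cc(c(=O)c2cc(F)c(cc21)N1CCNCC1)C(=O)O	fluoroquinolone-core
CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21	nalidixic-acid
Clc1cccc(Cl)c1N1CCN(CC1)CCCC(=O)c1ccc(F)cc1	butyrophenone-piperazine
COc1ccc2nc(sc2c1)S(=O)(=O)N	sulfonamide-benzothiazole
FC(F)(F)c1ccc(cc1)S(=O)(=O)NCCN	trifluoromethylsulfonamide
O=[N+]([O-])c1ccc(o1)/C=N/N1CC(=O)NC1=O	nitrofurantoin
CC(=O)Nc1nnc(s1)S(N)(=O)=O	acetazolamide
Clc1ccc(cc1)N1CCN(CCCCOc2ccc3CCC(=O)Nc3c2)CC1	aripiprazole-like
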