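name	exemplar	counter_exemplar
isopropyl	CC(C)O	CC(C)(C)O
amino	NCC	CNC
carboxylic acid ethyl ester	CCOC(C)=O	COC(C)=O
indole	c1ccc2[nH]ccc2c1	c1ccc2occc2c1
3,4,5-trimethoxyphenyl	Cc1cc(OC)c(OC)c(OC)c1	Cc1ccc(OC)c(OC)c1
morpholine	CN1CCOCC1	C1CCNCC1
thieno[2,3-b]pyrimidine	C1=CC2=C(S1)N=CN=C2	C1=CC2=NC=NC=C2S1
sulfone	CS(C)(=O)=O	CS(N)(=O)=O
tert-butyl	CC(C)(C)O	CC(C)O
vinyl	C=Cc1ccccc1	CC=CC
cyclopropyl	C1CC1c1ccccc1	C1CCC2CC2C1
cyclohexyl	CC1CCCCC1	CC1CCC(C)CC1
anellated cyclopropyl	C1CCC2CC2C1	C1CC12CCCCC2
anellated cycloheptyl	C1CCc2ccccc2CC1	C1CCCCCC1
dimethylamino	CN(C)C	CCNCC
diethylamino	CCN(CC)CC	CN(C)C
nitro	O=[N+]([O-])c1ccccc1	O=Nc1ccccc1
pyrrolidine	c1ccccc1N1CCCC1	C1CCNCC1
methylene hydroxy	OCc1ccccc1	CC(C)O
ethylene hydroxy	OCCc1ccccc1	OCc1ccccc1
oxolane	CC1CCCO1	c1ccoc1
carboxylic acid	OC(=O)c1ccccc1	COC(=O)c1ccccc1
carboxylic acid methyl ester	COC(C)=O	CCOC(C)=O
biphenyl	c1ccc(-c2ccccc2)cc1	C(c1ccccc1)c1ccccc1
stilbene	C(=C/c1ccccc1)\c1ccccc1	C=Cc1ccccc1
1,2,3-triazole	Cn1ccnn1	Cn1cncn1
1,2,4-triazole	Cn1cncn1	Cn1ccnn1
tetrazole	Cn1cnnn1	Cn1cncn1
pyrido[2,3-d]pyrimidine	C1=CC2=CN=CN=C2N=C1	c1ccc2ncncc2c1
1,3-dihydroisobenzofuran	C1OCc2ccccc21	C1Cc2ccccc2O1
chalcone	O=C(/C=C/c1ccccc1)c1ccccc1	O=C(CCc1ccccc1)c1ccccc1
hydroquinone	Oc1ccc(O)cc1	Oc1cccc(O)c1
2-methoxyphenyl	Cc1ccccc1OC	Cc1cccc(OC)c1
3-methoxyphenyl	Cc1cccc(OC)c1	Cc1ccccc1OC
2,5-dimethoxyphenyl	Cc1cc(OC)ccc1OC	Cc1ccc(OC)cc1OC
3,5-dimethoxyphenyl	Cc1cc(OC)cc(OC)c1	Cc1cc(OC)ccc1OC
unsubstituted thioamide	CC(N)=S	CNC(C)=S
oxazole	c1ocnc1	c1cnoc1
urea	NC(N)=O	CC(N)=O
thiourea	NC(N)=S	CC(N)=S
1,2,4-oxadiazole	Cc1ncon1	Cc1nnco1
1,3,4-thiadiazole	Cc1nncs1	Cc1ncsn1
piperazine	CN1CCNCC1	C1COCCN1
homo-piperazine	C1CNCCNC1	C1CNCCN1
piperidine	CN1CCCCC1	c1ccncc1
pyrimidine	Cc1ncccn1	c1cnccn1
pyrrole	Cn1cccc1	c1ccoc1
pyridine	c1ccncc1	c1ccccc1
thiophene	Cc1cccs1	c1ccoc1
imidazolidine	CN1CCN(C)C1	C1CNNC1
homo-piperidine	C1CCCNCC1	C1CCNCC1
homo-morpholine	C1CNCCOC1	C1COCCN1
oxazolidine	CN1CCOC1	C1CNOC1
isoxazole	c1cnoc1	c1ocnc1
imidazole	Cn1ccnc1	Cn1cccn1
furan	Cc1ccco1	Cc1cccs1
thiazole	c1cscn1	c1csnc1
pyrazole	Cn1cccn1	Cn1ccnc1
4-anilinopyrimidine	c1ccc(Nc2ccncn2)cc1	c1ccc(Nc2ncccn2)cc1
quinazoline	C1=CC=C2C(=C1)C=NC=N2	c1ccc2nccnc2c1
pyrrolo[3,2-d]pyrimidine	c1ncc2[nH]ccc2n1	c1ncc2cc[nH]c2n1
pyrimido[5,4-b]indole	c1ccc2c(c1)[nH]c1cncnc12	c1ccc2c(c1)[nH]c1ncncc12
quinoline	c1ccc2ncccc2c1	c1ccc2cnccc2c1
aniline	Nc1ccccc1	CNc1ccccc1
benzoyl	O=C(c1ccccc1)c1ccccc1	O=Cc1ccccc1
benzyl	NCc1ccccc1	Cc1ccccc1
cyano	N#Cc1ccccc1	c1ccncc1
9-deazapurine	c1ncc2[nH]ccc2n1	c1ncc2cc[nH]c2n1
ether	CCOCC	COc1ccccc1
ethylenediamine	CNCCNC	C1CNCCN1
methoxy	COc1ccccc1	CCOc1ccccc1
methoxyphenyl	COc1ccccc1	CCOc1ccccc1
phenol	Oc1ccccc1	COc1ccccc1
phenyl	Cc1ccccc1	c1ccncc1
resorcin	Oc1cccc(O)c1	Oc1ccc(O)cc1
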