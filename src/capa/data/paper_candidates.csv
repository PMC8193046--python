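id,name,smiles,zinc_id,molport_id,supplier,abcb1_ic50_um,abcc1_ic50_um,abcg2_ic50_um,screen_active_abcb1,screen_active_abcc1,screen_active_abcg2
16,"2-((2-(3,4-dihydro-2H-benzo[b][1,4]dioxepin-7-yl)pyrrolidin-1-yl)methyl)-5-(5-methyl-3-phenyl-isoxazol-4-yl)-1,3,4-oxadiazole",CC1=C(C2=NN=C(O2)CN3CCCC3C4=CC5=C(OCCCO5)C=C4)C(C6=CC=CC=C6)=NO1,08938070,005-547-575,ENAMINE Ltd.,,,,1,1,1
17,4-(1-(4-fluorophenyl)-1H-imidazole-5-carboxamido)cyclohexyl 1-(4-fluorophenyl)-1H-imidazole-5-carboxylate,FC1=CC=C(N2C=NC=C2C(NC3CCC(OC(C4=CN=CN4C5=CC=C(F)C=C5)=O)CC3)=O)C=C1,09672163,004-504-763,Ukr-OrgSynthesis Ltd.,,,,1,0,1
18,"3-(2-(4-(2-(azepan-1-yl)-2-oxoethyl)piperazin-1-yl)-2-oxoethyl)-5-(thiophen-2-yl)thieno[2,3-d]pyrimidin-4(3H)-one",O=C(N1CCN(CC1)CC(N2CCCCCC2)=O)CN3C=NC4=C(C3=O)C(C5=CC=CS5)=CS4,14239968,005-770-351,UkrOrgSynthesis Ltd.,,,,0,1,1
19,"(4-(benzo[d][1,3]dioxol-5-ylmethyl)piperazin-1-yl)(1-(5-(pyrrolidin-1-yl)-1,3,4-thiadiazol-2-yl)-1H-pyrrol-2-yl)methanone",O=C(C1=CC=CN1C2=NN=C(N3CCCC3)S2)N4CCN(CC4)CC5=CC=C6OCOC6=C5,15731308,007-821-780,ChemDiv Inc.,,,,1,0,1
20,"4-(3-(6-(pyridin-2-yl)-4,6,7a,12a-tetrahydro-1H-benzo[4,5]imidazo[1,2-a][1,3,5]triazino[1,2-c][1,3,5]triazin-2(3H)-yl)propyl)morpholine",N1(CCOCC1)CCCN2CNC3=NC(N4C(N3C2)N=C5C=CC=CC45)C6=CC=CC=N6,20567796,005-912-631,Vitas-M Laboratory Ltd.,,,,0,0,0
21,"N-((1-(5-(4-benzylpiperazin-1-yl)-1,3,4-thiadiazol-2-yl)-1H-pyrrol-2-yl)methyl)-2-(pyrrolidin-1-yl)ethan-1-amine",N1(CCCC1)CCNCC2=CC=CN2C3=NN=C(N4CCN(CC4)CC5=CC=CC=C5)S3,20576334,007-776-896,ChemDiv Inc.,,,,1,0,0
22,4-(2-(3-(3-(isoquinolin-4-yl)phenyl)-1H-pyrazol-1-yl)ethyl)morpholine,N1(C=CC(C2=CC=CC(C3=CN=CC4=CC=CC=C34)=C2)=N1)CCN5CCOCC5,23213965,005-039-609,ChemBridge Corporation,,,,1,1,1
23,"1-(4-(6-(1H-imidazol-1-yl)-2-methylpyrimidin-4-yl)piperazin-1-yl)-2,2-diphenylethan-1-one",CC1=NC(N2C=CN=C2)=CC(N3CCN(C(C(C4=CC=CC=C4)C5=CC=CC=C5)=O)CC3)=N1,65362307,016-587-938,ChemBridge Corporation,4.01,14.8,9.27,1,1,1
24,1-(6-(1H-pyrazol-1-yl)pyrimidin-4-yl)-N-benzyl-N-(pyridin-2-yl)piperidine-3-carboxamide,O=C(N(C1=CC=CC=N1)CC2=CC=CC=C2)C3CCCN(C4=CC(N5C=CC=N5)=NC=N4)C3,70638100,019-920-623,Life Chemicals Inc.,,,,1,1,1
25,"3-(2-(4-(6-fluorobenzo[d]isoxazol-3-yl)piperidin-1-yl)-2-oxoethyl)-2-hydroxy-3,4-dihydro-5H-benzo[e][1,4]diazepin-5-one",OC1=NC2=C(C(NC1CC(N3CCC(C4=NOC5=C4C=CC(F)=C5)CC3)=O)=O)C=CC=C2,95474733,027-849-694,Vitas-M Laboratory Ltd.,,,,0,0,1
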