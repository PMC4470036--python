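name	source	grade	sex	FGFR3_mut	FGFR3_cn	PIK3CA_mut	PIK3CA_cn	HRAS_mut	HRAS_cn	KRAS_mut	KRAS_cn	NRAS_mut	NRAS_cn	TERT_mut	TERT_cn	INK4A_mut	INK4A_cn	PTEN_mut	PTEN_cn	TP53_mut	TP53_cn	instability_group
253J	UCC	G4	F	WT:1,4	.	E545G:2,4	.	WT:4	.	WT:1	.	WT:4	.	WT:11	.	.	HD:1,4	.	.	WT:3	N:3	intermediate
5637	UCC	G2	M	WT:1,4	.	WT:1,4	.	WT:1,4	.	WT:4	.	WT:1	.	Mut:11	.	.	WT:1,4	.	.	c.839G>C:1,2,3	N:1,2,3	intermediate
575A	UCC	G3	M	WT:1,4	.	WT:4	.	.	.	.	.	.	.	.	.	.	WT:0	.	.	WT:1	LOH:1	intermediate
639V	UCC	G3	M	WT:1,4;R248C:2	.	A1066V:1,2,4	.	WT:1,4	.	WT:1;G12D:2	.	WT:1;H131R:2	.	Mut:11	.	.	LOH:4	.	.	c.743G>A:1,2,3	N:1,2,3	high
92-1	UCC	G3	F	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11,12	.	.	WT:6,4	.	.	cd158&162&228&280&294:6,8	N:6,8	intermediate
96-1	UCC	G2/3	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11,12	.	.	HD:6	.	.	cd175:6,8	N:6,8	intermediate
97-1	UCC	G1/2	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:11	.	.	HD:6	.	.	WT:6,8	LOH:6,8	low
97-18	UCC	G3	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11,12	.	.	LOH:4	.	.	cd220:8	LOH:8	high
97-24	.	G3	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11,12	.	.	WT:4	.	.	cd275:8	N:8	high
97-7	UCC	G2/3	M	S249C:1	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11	.	.	WT:4	.	.	cd128:8	N:8	high
BC61	UCC	G2	M	G372C:4,10	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	.	.	.	WT:4	.	.	WT:0	N:0	low
HT1197	UCC	G4	M	S249C:1,4	.	E545K:1,4	.	WT:1,4	.	WT:1	.	WT:1;Q61R:4	.	Mut:11,12	.	.	WT:1	.	.	WT:1;c.1094A>G:3	.	.
HT1376	UCC	G3	F	WT:1,4	.	WT:1,4	.	WT:1,4	.	WT:1	.	WT:1	.	Mut:11	.	.	WT:1,4	.	.	c.749C>T:1,2,3	LOH:1,2,3	low
HU456	.	G1	M	WT:4	.	.	.	G12S:4	.	WT:4	.	.	.	WT:12	.	.	HD:4	.	.	WT:7	N:7	intermediate
J82	EC	G3	M	WT:1;K652E:2,4	.	P124L:1,2,4	.	WT:1,4	.	WT:1	.	WT:1	.	Mut:11	.	.	WT:1,4	.	.	c.960G>C&c.820G>T&c.811G>A&c.783_919del137:1,2,3	N:1,2,3	intermediate
JON	UCC	.	.	WT:1;S249C:1	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11;WT:12	.	.	.	.	.	Mut:4	.	.
KK47	.	G1	M	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	WT:12	.	.	WT:4	.	.	.	N:0	high
LGWO1 G600	.	.	.	WT:1,4	.	WT:4	.	WT:4	.	G12C:4	.	WT:4	.	WT:12	.	.	HD:4	.	.	.	LOH:0	low
MGH-U3	UCC	G1	M	Y375C:4;Y373C:1	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11,12	.	.	HD:4	.	.	WT:4	N:4	low
MGH-U4	atypia	G1	M	WT:1,4	.	H1047R:4	.	.	.	.	.	.	.	Mut:12	.	.	HD:4	.	.	WT:4	N:4	low
PSI	UCC	G3	M	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	Mut:12	.	.	.	.	.	WT:7	.	.
RT112	UCC	G2	F	WT:1,2,4;FGFR3-TACC3_fusion:13	Amp:4	WT:1,4	.	WT:1,4	.	WT:1	.	WT:1	.	Mut:11,12	.	.	HD:1,4	.	.	c.743G>A&c.548C>G:1,2,3	LOH:1,2,3	low
RT4	UCC	G1	M	WT:1,4;FGFR3-TACC3_fusion:13	Amp:4	WT:1	.	WT:0	.	WT:1	.	WT:1	.	Mut:11,12	.	.	HD:1,4	.	.	WT:1,3	LOH:1,3	low
SCaBER	SCC	.	M	WT:1,2,4	.	WT:0	.	WT:4	.	WT:4	.	WT:1	.	Mut:11,12	.	.	LOH:4	.	.	c.329G>T:2,3	LOH:2,3	intermediate
SW-1710	UCC	.	F	WT:1,2,4	.	WT:1,4	.	WT:1,4	.	WT:1	.	WT:0	.	Mut:11,12	.	.	HD:1	.	.	c.817C>T:1,2,3	LOH:1,2,3	high
SW-800	UCC	.	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	HD:4	.	.	WT:4	N:4	low
SW-850	.	.	.	WT:4	.	WT:4	.	G12V:4	.	WT:4	.	WT:4	.	.	.	.	.	.	.	.	.	.
SW-780	UCC	G1	F	WT:1,2;S773F:2;FGFR3-BAIAP2L1_fusion:13	.	WT:1	.	WT:1	.	WT:1	.	WT:1	.	Mut:12	.	.	HD:4	.	.	WT:1	N:1	low
T24	EC	G3	F	WT:1,4	.	WT:1,4	.	G12V:1,4	.	WT:1	.	WT:1	.	Mut:11,12	.	.	WT:1;LOH:4	.	.	c.378C>G:1,3	N:1,3	low
TCCSUP	UCC	G4	F	WT:1,4	.	E545K:1	.	WT:1,4	.	WT:1	.	WT:1	.	Mut:11,12	.	.	WT:1	.	.	c.1045G>T:1,3	LOH:1,3	intermediate
UM-UC-1	UCC-LN	G2	M	WT:1	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	.	.	.	HD:4	.	.	c.454C>T:2,3,5	LOH:2,3,5	intermediate
UM-UC-2	UCC-CIS	.	M	WT:1	.	.	.	.	.	.	.	.	.	Mut:12	.	.	.	.	.	WT:5	.	.
UM-UC-3	UCC	.	M	WT:1,4	.	WT:1,4	.	WT:1,4	.	G12C:1,2,4	.	WT:1	.	Mut:11	.	.	HD:1;WT:4	.	.	c.338T>G:1,3,5,9	N:1,3,5,9	high
UM-UC-4	UCC-LC	.	F	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	.	.	.	.	.	.	.	LOH:0	high
UM-UC-5	.	.	F	WT:4	.	E545K:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	HD:4	.	.	.	LOH:0	intermediate
UM-UC-6	UCC	.	M	WT:1;R248C:4	.	E545K:4	.	WT:4	.	.	.	.	.	.	.	.	HD:4	.	.	WT:1,5,9	LOH:1,5,9	low
UM-UC-7	.	.	M	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	Mut:12	.	.	WT:4	.	.	.	LOH:0	intermediate
UM-UC-9	UCC	.	.	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	Mut:12	.	.	LOH:4	.	.	Mut:5,9	LOH:5,9	intermediate
UM-UC-10	UCC	.	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	.	.	.	Mut:5	.	.
UM-UC-11	UCC	.	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	HD:4	.	.	WT:5	N:5	high
UM-UC-12	UCC	.	M	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	.	.	.	.	.	N:0	high
UM-UC-13	UCC-LN	.	M	WT:4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	LOH:4	.	.	Mut:5	N:5	high
UM-UC-14	UCC	.	M	S249C:1	.	WT:4	.	.	.	.	.	.	.	Mut:11,12	.	.	HD:4	.	.	Mut:5,9	LOH:5,9	low
UM-UC-15	.	.	.	Y375C:4	.	E545K:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:12	.	.	.	.	.	.	.	.
UM-UC-17	.	.	.	S249C:4	.	WT:4	.	.	.	.	.	.	.	.	.	.	HD:4	.	.	.	LOH:0	intermediate
UM-UC-18	.	.	.	WT:4	.	WT:4	.	Q61K:4	.	WT:4	.	WT:4	.	Mut:12	.	.	WT:4	.	.	.	N:0	high
VM-CUB-1	EC	G2	M	WT:1	.	WT:1;E542K&E674Q:2	.	WT:1	.	WT:1	.	WT:1	.	Mut:11,12	.	c.322G>C:1	LOH:4	.	.	c.524G>A&c.378C>G:1,2,3	LOH:1,2,3	high
VM-CUB-2	EC	.	M	WT:1,4	.	WT:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11	.	.	HD:1,4	.	.	c.473G>T&c.488A>G:3	LOH:3	high
VM-CUB-3	EC	G3	M	WT:1,4	.	E545K:4	.	WT:4	.	WT:4	.	WT:4	.	Mut:11	.	.	HD:4	.	.	c.833C>T:3	N:3	low
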