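water	O
methanol	CO
ethanol	CCO
acetone	CC(C)=O
acetonitrile	CC#N
toluene	Cc1ccccc1
dichloromethane	ClCCl
chloroform	ClC(Cl)Cl
tetrahydrofuran	C1CCOC1
ethyl acetate	CCOC(C)=O
diethyl ether	CCOCC
dimethylformamide	CN(C)C=O
dimethyl sulfoxide	CS(C)=O
pyridine	c1ccncc1
hexane	CCCCCC
heptane	CCCCCCC
1,4-dioxane	C1COCCO1
isopropanol	CC(C)O
n-butanol	CCCCO
xylene	Cc1ccccc1C
sodium chloride	[Na+].[Cl-]
sodium sulfate	[Na+].[Na+].[O-]S([O-])(=O)=O
magnesium sulfate	[O-]S([O-])(=O)=O.[Mg+2]
sodium bicarbonate	[Na+].OC([O-])=O
hydrochloric acid	Cl
sulfuric acid	OS(O)(=O)=O
acetic acid	CC(O)=O
trifluoroacetic acid	OC(=O)C(F)(F)F
sodium hydroxide	[Na+].[OH-]
lithium hydroxide	[Li+].[OH-]
potassium carbonate	[K+].[K+].[O-]C([O-])=O
cesium carbonate	[Cs+].[Cs+].[O-]C([O-])=O
ammonium chloride	[NH4+].[Cl-]
triethylamine	CCN(CC)CC
N,N-diisopropylethylamine	CCN(C(C)C)C(C)C
benzoic acid	OC(=O)c1ccccc1
aniline	Nc1ccccc1
benzylamine	NCc1ccccc1
phenol	Oc1ccccc1
benzaldehyde	O=Cc1ccccc1
morpholine	C1COCCN1
pyrrolidine	C1CCNC1
piperidine	C1CCNCC1
imidazole	c1cnc[nH]1
EDC	CCN=C=NCCCN(C)C
HOBt	On1nnc2ccccc21
4-dimethylaminopyridine	CN(C)c1ccncc1
benzyl bromide	BrCc1ccccc1
iodomethane	CI
sodium borohydride	[Na+].[BH4-]
sodium hydride	[Na+].[H-]
triphenylphosphine	c1ccc(cc1)P(c1ccccc1)c1ccccc1
nitromethane	C[N+]([O-])=O
malononitrile	N#CCC#N
dimethyl malonate	COC(=O)CC(=O)OC
4-nitrobenzaldehyde	O=Cc1ccc(cc1)[N+]([O-])=O
4-fluoroaniline	Nc1ccc(F)cc1
3-bromopyridine	Brc1cccnc1
2-aminopyridine	Nc1ccccn1
4-bromoanisole	COc1ccc(Br)cc1
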