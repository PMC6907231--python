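# seed reagent/catalyst drop-down library: display name <TAB> SMILES
Triethylamine	CCN(CC)CC
DIPEA	CCN(C(C)C)C(C)C
Pyridine	c1ccncc1
DMAP	CN(C)c1ccncc1
DBU	C1CCC2=NCCCN2CC1
Sodium hydride	[H-].[Na+]
Potassium carbonate	O=C([O-])[O-].[K+].[K+]
Cesium carbonate	O=C([O-])[O-].[Cs+].[Cs+]
Potassium tert-butoxide	CC(C)(C)[O-].[K+]
n-Butyllithium	[Li]CCCC
Sodium borohydride	[Na+].[BH4-]
Lithium aluminium hydride	[Li+].[AlH4-]
Palladium on carbon	[Pd]
Tetrakis(triphenylphosphine)palladium	c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.[Pd]
Triphenylphosphine	c1ccc(P(c2ccccc2)c2ccccc2)cc1
Hydrochloric acid	Cl
Sulfuric acid	OS(=O)(=O)O
Trifluoroacetic acid	OC(=O)C(F)(F)F
p-Toluenesulfonic acid	Cc1ccc(S(=O)(=O)O)cc1
Mesyl chloride	CS(=O)(=O)Cl
Tosyl chloride	Cc1ccc(S(=O)(=O)Cl)cc1
Thionyl chloride	O=S(Cl)Cl
DCC	C1CCC(N=C=NC2CCCCC2)CC1
EDC	CCN=C=NCCCN(C)C
NBS	O=C1CCC(=O)N1Br
mCPBA	O=C(OO)c1cccc(Cl)c1
Copper(I) iodide	[Cu]I
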