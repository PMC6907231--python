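# seed name library: key <TAB> SMILES <TAB> source (internal | corpus | editor)
DMF	CN(C)C=O	internal
DMSO	CS(C)=O	internal
THF	C1CCOC1	internal
DCM	ClCCl	internal
MeOH	CO	internal
EtOH	CCO	internal
iPrOH	CC(C)O	internal
MeCN	CC#N	internal
acetonitrile	CC#N	corpus
toluene	Cc1ccccc1	corpus
benzene	c1ccccc1	corpus
dioxane	C1COCCO1	corpus
1,4-dioxane	C1COCCO1	corpus
Et2O	CCOCC	internal
ether	CCOCC	corpus
EtOAc	CCOC(C)=O	internal
ethyl acetate	CCOC(C)=O	corpus
hexane	CCCCCC	corpus
acetone	CC(C)=O	corpus
water	O	corpus
H2O	O	internal
chloroform	C(Cl)(Cl)Cl	corpus
CHCl3	C(Cl)(Cl)Cl	internal
NEt3	CCN(CC)CC	internal
Et3N	CCN(CC)CC	internal
TEA	CCN(CC)CC	internal
DIPEA	CCN(C(C)C)C(C)C	internal
pyridine	c1ccncc1	corpus
DMAP	CN(C)c1ccncc1	internal
DBU	C1CCC2=NCCCN2CC1	internal
NaH	[H-].[Na+]	internal
NaOH	[OH-].[Na+]	internal
KOH	[OH-].[K+]	internal
K2CO3	O=C([O-])[O-].[K+].[K+]	internal
Na2CO3	O=C([O-])[O-].[Na+].[Na+]	internal
Cs2CO3	O=C([O-])[O-].[Cs+].[Cs+]	internal
NaHCO3	O=C(O)[O-].[Na+]	internal
KOtBu	CC(C)(C)[O-].[K+]	internal
n-BuLi	[Li]CCCC	internal
NaBH4	[Na+].[BH4-]	internal
LiAlH4	[Li+].[AlH4-]	internal
H2	[H][H]	internal
Pd/C	[Pd]	internal
Pd(PPh3)4	c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.c1ccc(P(c2ccccc2)c2ccccc2)cc1.[Pd]	internal
PPh3	c1ccc(P(c2ccccc2)c2ccccc2)cc1	internal
HCl	Cl	internal
H2SO4	OS(=O)(=O)O	internal
HNO3	O[N+](=O)[O-]	internal
AcOH	CC(=O)O	internal
acetic acid	CC(=O)O	corpus
TFA	OC(=O)C(F)(F)F	internal
TsOH	Cc1ccc(S(=O)(=O)O)cc1	internal
MsCl	CS(=O)(=O)Cl	internal
TsCl	Cc1ccc(S(=O)(=O)Cl)cc1	internal
SOCl2	O=S(Cl)Cl	internal
oxalyl chloride	O=C(Cl)C(=O)Cl	corpus
DCC	C1CCC(N=C=NC2CCCCC2)CC1	internal
EDC	CCN=C=NCCCN(C)C	internal
HOBt	On1nnc2ccccc21	internal
CDI	O=C(n1ccnc1)n1ccnc1	internal
NBS	O=C1CCC(=O)N1Br	internal
NCS	O=C1CCC(=O)N1Cl	internal
I2	II	internal
Br2	BrBr	internal
mCPBA	O=C(OO)c1cccc(Cl)c1	internal
H2O2	OO	internal
KMnO4	[K+].[O-][Mn](=O)(=O)=O	internal
OsO4	O=[Os](=O)(=O)=O	internal
AgNO3	[Ag+].[O-][N+](=O)[O-]	internal
CuI	[Cu]I	internal
ZnCl2	Cl[Zn]Cl	internal
MgSO4	[Mg+2].[O-]S(=O)(=O)[O-]	internal
Na2SO4	[Na+].[Na+].[O-]S(=O)(=O)[O-]	internal
NH4Cl	[NH4+].[Cl-]	internal
benzaldehyde	O=Cc1ccccc1	corpus
aniline	Nc1ccccc1	corpus
phenol	Oc1ccccc1	corpus
morpholine	C1COCCN1	corpus
piperidine	C1CCNCC1	corpus
imidazole	c1c[nH]cn1	corpus
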