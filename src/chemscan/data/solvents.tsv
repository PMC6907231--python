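# seed solvent library: one SMILES per line (optionally name <TAB> smiles)
water	O
THF	C1CCOC1
DCM	ClCCl
chloroform	C(Cl)(Cl)Cl
DMF	CN(C)C=O
DMSO	CS(C)=O
MeOH	CO
EtOH	CCO
iPrOH	CC(C)O
MeCN	CC#N
toluene	Cc1ccccc1
benzene	c1ccccc1
dioxane	C1COCCO1
Et2O	CCOCC
EtOAc	CCOC(C)=O
hexane	CCCCCC
acetone	CC(C)=O
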