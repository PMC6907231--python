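# seed superatom library: label <TAB> expansion SMILES with dummy-atom attachment marker(s)
# multi-attachment expansions order their markers by atom-map index ([*:1], [*:2], ...)
Me	[*]C
Et	[*]CC
Pr	[*]CCC
iPr	[*]C(C)C
nBu	[*]CCCC
tBu	[*]C(C)(C)C
Ph	[*]c1ccccc1
Bn	[*]Cc1ccccc1
Bz	[*]C(=O)c1ccccc1
Ac	[*]C(C)=O
Boc	[*]C(=O)OC(C)(C)C
Cbz	[*]C(=O)OCc1ccccc1
Ts	[*]S(=O)(=O)c1ccc(C)cc1
Ms	[*]S(C)(=O)=O
Tf	[*]S(=O)(=O)C(F)(F)F
OMe	[*]OC
OEt	[*]OCC
OAc	[*]OC(C)=O
OBn	[*]OCc1ccccc1
OTs	[*]OS(=O)(=O)c1ccc(C)cc1
OMs	[*]OS(C)(=O)=O
OTf	[*]OS(=O)(=O)C(F)(F)F
OH	[*]O
NH2	[*]N
NHMe	[*]NC
NMe2	[*]N(C)C
NEt2	[*]N(CC)CC
NO2	[*][N+](=O)[O-]
CN	[*]C#N
CF3	[*]C(F)(F)F
CCl3	[*]C(Cl)(Cl)Cl
CO2H	[*]C(=O)O
COOH	[*]C(=O)O
CO2Me	[*]C(=O)OC
CO2Et	[*]C(=O)OCC
CHO	[*]C=O
SMe	[*]SC
SO3H	[*]S(=O)(=O)O
TMS	[*][Si](C)(C)C
TBS	[*][Si](C)(C)C(C)(C)C
Piv	[*]C(=O)C(C)(C)C
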