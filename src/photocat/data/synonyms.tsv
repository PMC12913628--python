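# raw name -> canonical common name (tab-separated); matching is
# case- and whitespace-insensitive.
trifluoromethanesulfonic acid	TfOH
triflic acid	TfOH
CF3SO3H	TfOH
trifluoroacetic acid	TFA
potassium carbonate	K2CO3
cesium carbonate	Cs2CO3
caesium carbonate	Cs2CO3
tris(bipyridine)ruthenium(II) chloride	Ru(bpy)3Cl2
Ru(bpy)3(PF6)2	Ru(bpy)3Cl2
tris(2-phenylpyridine)iridium	Ir(ppy)3
fac-Ir(ppy)3	Ir(ppy)3
eosin	Eosin Y
9-mesityl-10-methylacridinium	Acr+-Mes
acetonitrile	MeCN
CH3CN	MeCN
dimethyl sulfoxide	DMSO
dimethylsulfoxide	DMSO
N,N-dimethylformamide	DMF
dichloromethane	DCM
methylene chloride	DCM
tetrabutylammonium bromide	TBAB
triphenylphosphine	PPh3
lithium bromide	LiBr
no photocatalyst	autocatalysis
self-photosensitized	autocatalysis
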