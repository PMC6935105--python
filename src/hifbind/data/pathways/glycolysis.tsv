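pathway	glycolysis
glucose_import	SLC2A1,SLC2A3
hexokinase	HK1,HK2
glucose6P_isomerase	GPI
phosphofructokinase	PFKL,PFKM,PFKP
F26BP_regulation	PFKFB3,PFKFB4	curated
aldolase	ALDOA,ALDOC
triosephosphate_isomerase	TPI1	curated
GAPDH	GAPDH	curated
phosphoglycerate_kinase	PGK1
phosphoglycerate_mutase	PGAM1	curated
enolase	ENO1,ENO2
pyruvate_kinase	PKM
pyruvate_dehydrogenase_kinase	PDK1,PDK2,PDK3
lactate_dehydrogenase	LDHA	curated
lactate_export	SLC16A3
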