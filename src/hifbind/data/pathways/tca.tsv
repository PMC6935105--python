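pathway	tca
pyruvate_dehydrogenase	PDHA1,PDHB,DLAT	curated
citrate_synthase	CS	curated
aconitase	ACO2	curated
isocitrate_dehydrogenase	IDH2,IDH3A,IDH3B,IDH3G	curated
akg_dehydrogenase	OGDH,DLST,DLD	curated
succinyl_CoA_synthetase	SUCLA2,SUCLG1,SUCLG2	curated
succinate_dehydrogenase	SDHA,SDHB,SDHC,SDHD	curated
fumarase	FH	curated
malate_dehydrogenase	MDH2	curated
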