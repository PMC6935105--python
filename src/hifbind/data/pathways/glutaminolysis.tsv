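pathway	glutaminolysis
glutamine_import	SLC1A5
glutaminase	GLS,GLS2
glutamine_synthetase	GLUL
glutamate_dehydrogenase	GLUD1	curated
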