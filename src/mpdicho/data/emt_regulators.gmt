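EMT_REGULATORS	EMT transcription factors used as the migration/invasion signature	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2	GLI1	GLI2	KLF4
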