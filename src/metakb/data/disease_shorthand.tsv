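# Per-source shorthand disease codes (internal representations that are not
# ontology synonyms). Deliberately sparse: unlisted shorthand stays unmapped.
source	shorthand	doid
CGI	L	DOID:1324
CGI	OV	DOID:2394
MMatch	CRC	DOID:9256
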