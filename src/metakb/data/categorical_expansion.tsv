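# Per-source expansion of categorical variant concepts to the constituent
# alleles that source considers members of the class. Alleles are |-separated
# labels resolved through the coordinate lookup. No expansion happens for
# (source, gene, label) triples absent from this table.
source	gene	label	alleles
CGI	BRAF	oncogenic mutation	V600E|V600K|G469A|K601E
CGI	KRAS	oncogenic mutation	G12D|G12C|G12V|Q61H|A146T
CGI	PIK3CA	oncogenic mutation	E545K|H1047R|R88Q
CGI	EGFR	oncogenic mutation	L858R|T790M|G719A|S768I
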