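# Variant-name -> coordinate lookup (stand-in for a somatic mutation catalog).
# Coordinates are 1-based inclusive. Row kinds, decided by the allele columns:
#   ref and alt set            -> allele-specific substitution/delins
#   ref="-", alt set           -> insertion after base `start` (start == end)
#   ref="-", alt="-"           -> region-only record (categorical variant)
# Keys are (gene, lower-cased variant label).
gene	variant	assembly	chromosome	start	end	ref	alt
BRAF	V600E	GRCh37	7	140453136	140453136	A	T
BRAF	V600K	GRCh37	7	140453136	140453137	AC	TT
KRAS	G12D	GRCh37	12	25398284	25398284	C	T
KRAS	G12C	GRCh37	12	25398285	25398285	C	A
KRAS	G12V	GRCh37	12	25398284	25398284	C	A
PIK3CA	E545K	GRCh37	3	178936091	178936091	G	A
PIK3CA	H1047R	GRCh37	3	178952085	178952085	A	G
EGFR	L858R	GRCh37	7	55259515	55259515	T	G
EGFR	T790M	GRCh37	7	55249071	55249071	C	T
NRAS	Q61K	GRCh37	1	115256530	115256530	G	T
BRAF	G469A	GRCh37	7	140481402	140481402	C	G
BRAF	K601E	GRCh37	7	140453096	140453096	T	C
KRAS	Q61H	GRCh37	12	25380275	25380275	T	G
KRAS	A146T	GRCh37	12	25378561	25378561	C	T
PIK3CA	R88Q	GRCh37	3	178916876	178916876	G	A
EGFR	G719A	GRCh37	7	55241707	55241707	G	C
EGFR	S768I	GRCh37	7	55249005	55249005	G	T
TP53	R175H	GRCh37	17	7578406	7578406	C	T
ALK	F1174L	GRCh37	2	29443695	29443695	G	T
ERBB2	Y772_A775dup	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	M774insAYVM	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	M774INSAYVM	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	A775_G776insYVMA	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	E770delinsEAYVM	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	inframe insertion A775YVMA	GRCh37	17	37880979	37880990	TACGTGATGGCA	TACGTGATGGCATACGTGATGGCA
ERBB2	exon 20 insertion	GRCh37	17	37880900	37881049	-	-
ERBB2	exon 20 insertions	GRCh37	17	37880900	37881049	-	-
ERBB2	exon(s) 20 insertion	GRCh37	17	37880900	37881049	-	-
ERBB2	proximal exon 20	GRCh37	17	37880900	37880999	-	-
ERBB2	kinase domain mutation	GRCh37	17	37879900	37881899	-	-
EGFR	exon 19 deletion	GRCh37	7	55242415	55242513	-	-
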