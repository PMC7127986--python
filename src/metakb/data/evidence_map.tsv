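# Harmonized evidence map: knowledgebase-specific evidence codes -> AMP/ASCO/CAP
# levels. Levels A,B = tier I; C,D = tier II. One row per member code; composite
# codes as printed in source exports resolve on any listed member.
source	code	level
CIViC	Level A	A
CIViC	Level B	B
CIViC	Level C	C
CIViC	Predictive level C	C
CIViC	Nonpredictive level C	D
CIViC	Level D	D
CIViC	Level E	D
OncoKB	Level 1	A
OncoKB	Level 2A	A
OncoKB	2A	A
OncoKB	R1	A
OncoKB	Level 3A	B
OncoKB	Level 2B	C
OncoKB	Level 3B	C
OncoKB	Level 4	D
JAX-CKB	Guideline	A
JAX-CKB	FDA approved	A
JAX-CKB	Phase III	B
JAX-CKB	Clinical study	C
JAX-CKB	Phase I	C
JAX-CKB	Phase II	C
JAX-CKB	Phase 0	D
JAX-CKB	Preclinical	D
CGI	Clinical practice	A
CGI	Clinical trials III-IV	B
CGI	Clinical trials I-II	C
CGI	Case reports	C
CGI	Early trials	C
CGI	Preclinical data	D
MMatch	Level 1A	A
MMatch	Level 1B	B
MMatch	Level 2C	C
MMatch	Level 2D	D
PMKB	Tier 1	A
PMKB	Tier 2	C
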