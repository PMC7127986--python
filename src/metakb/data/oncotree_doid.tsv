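# Oncotree code -> disease-ontology identifier. One-to-many codes are listed
# on several rows and carry needs_review=1, mirroring mappings that required
# manual review.
oncotree_code	doid	needs_review
LUAD	DOID:3910	0
LUSC	DOID:3907	0
NSCLC	DOID:3908	0
BRCA	DOID:3459	0
IDC	DOID:3008	0
ILC	DOID:0050938	0
COADREAD	DOID:9256	0
COAD	DOID:219	0
SKCM	DOID:8923	0
MEL	DOID:1909	0
CLL	DOID:1040	0
ALL	DOID:9952	0
BLCA	DOID:11054	0
HGSOC	DOID:2394	0
GB	DOID:0060108	0
BONE	DOID:184	0
SARC	DOID:1115	0
MIXED	DOID:1612	1
MIXED	DOID:1324	1
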