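# Secondary drug synonym table (compound-registry style; queried when the
# primary table misses). Carries brand names and development codes.
name	id	label
herceptin	CHEMBL1201585	trastuzumab
zelboraf	CHEMBL1229517	vemurafenib
tafinlar	CHEMBL2028663	dabrafenib
mekinist	CHEMBL2103875	trametinib
tykerb	CHEMBL554	lapatinib
iressa	CHEMBL939	gefitinib
tarceva	CHEMBL553	erlotinib
tagrisso	CHEMBL3353410	osimertinib
gilotrif	CHEMBL1173655	afatinib
gleevec	CHEMBL941	imatinib
erbitux	CHEMBL1201577	cetuximab
kadcyla	CHEMBL1743082	trastuzumab emtansine
ap32788	CHEMBL4650485	mobocertinib
tak-788	CHEMBL4650485	mobocertinib
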