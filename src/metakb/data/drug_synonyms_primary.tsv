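# Primary drug synonym table (ChEMBL-style identifiers; queried first).
name	id	label
afatinib	CHEMBL1173655	afatinib
rapamycin	CHEMBL413	sirolimus
sirolimus	CHEMBL413	sirolimus
vemurafenib	CHEMBL1229517	vemurafenib
dabrafenib	CHEMBL2028663	dabrafenib
trametinib	CHEMBL2103875	trametinib
trastuzumab	CHEMBL1201585	trastuzumab
trastuzumab emtansine	CHEMBL1743082	trastuzumab emtansine
ado-trastuzumab emtansine	CHEMBL1743082	trastuzumab emtansine
neratinib	CHEMBL180022	neratinib
lapatinib	CHEMBL554	lapatinib
gefitinib	CHEMBL939	gefitinib
erlotinib	CHEMBL553	erlotinib
osimertinib	CHEMBL3353410	osimertinib
dacomitinib	CHEMBL2110732	dacomitinib
crizotinib	CHEMBL601719	crizotinib
imatinib	CHEMBL941	imatinib
cetuximab	CHEMBL1201577	cetuximab
panitumumab	CHEMBL1201827	panitumumab
alpelisib	CHEMBL2396661	alpelisib
everolimus	CHEMBL1908360	everolimus
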