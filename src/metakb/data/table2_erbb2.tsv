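# ERBB2 exon-20 duplication (NP_004439.2:p.Y772_A775dup) worked example: every
# evidence row describing this alteration across the six knowledgebases, with
# each source's own variant spelling, evidence code, cited documents, therapy
# and disease wording. Multiple documents are |-separated. The interpretation
# column is the verbatim assertion text.
resource	variant	evidence	documents	drugs	disease	direction	interpretation
CIViC	M774INSAYVM	Level B, 2-star	PMID: 25899785	dacomitinib	NSCLC	does_not_support	Does not support sensitivity/response to dacomitinib in NSCLC
CIViC	M774INSAYVM	Level C, 4-star	PMID: 26559459	afatinib	lung adenocarcinoma	supports	Supports sensitivity/response to afatinib in lung adenocarcinoma
CIViC	M774INSAYVM	Level C, 3-star	PMID: 22325357	afatinib	lung adenocarcinoma	supports	Supports sensitivity/response to afatinib in lung adenocarcinoma
CIViC	M774INSAYVM	Level C, 3-star	PMID: 25789838	trastuzumab emtansine	lung adenocarcinoma	supports	Supports sensitivity/response to trastuzumab emtansine in lung adenocarcinoma
CIViC	M774INSAYVM	Level D, 3-star	PMID: 19122144	afatinib and rapamycin (combination)	NSCLC	supports	Supports sensitivity/response to afatinib and rapamycin (combination) in NSCLC
CIViC	Kinase domain mutation	Level C, 4-star	PMID: 26598547	trastuzumab	lung adenocarcinoma	supports	Supports sensitivity/response to trastuzumab in lung adenocarcinoma
CIViC	Kinase domain mutation	Level C, 3-star	PMID: 22325357	afatinib	lung adenocarcinoma	supports	Supports sensitivity/response to afatinib in lung adenocarcinoma
OncoKB	Exon 20 insertions	Level 4	10.1158/1538-7445.AM2016-2644	AP32788	NSCLC	supports	Supports response to AP32788 in NSCLC
OncoKB	Oncogenic mutations	Level 3A	PMID: 23220880|10.1158/1538-7445.AM2017-CT001	neratinib	breast cancer and NSCLC	supports	Supports response to neratinib in breast cancer and NSCLC
CGI	inframe insertion A775YVMA	Early trials	10.1200/JCO.2017.35.15_suppl.8510	ado-trastuzumab emtansine	lung cancer	supports	Responsive to ado-trastuzumab emtansine in lung cancer
CGI	inframe insertion A775YVMA	Early trials	10.1158/1538-7445.AM2017-CT001	neratinib	cancer	supports	Responsive to neratinib in cancer
CGI	proximal exon 20	Early trials	PMID: 26598547|10.1200/JCO.2017.35.15_suppl.9071	afatinib, neratinib, lapatinib or trastuzumab	lung adenocarcinoma	supports	Responsive to afatinib, neratinib, lapatinib or trastuzumab in lung adenocarcinoma
PMKB	exon(s) 20 insertion	Tier 2	PMID: 22761469|PMID: 16818618|PMID: 25152623		lung adenocarcinoma	supports	Associated with sensitivity to some ERBB2 inhibitors in lung adenocarcinoma
JAX-CKB	Y772_A775dup	Clinical study	PMID: 26964772	afatinib	lung adenocarcinoma	conflicting	Conflicting response to afatinib in lung adenocarcinoma
JAX-CKB	Y772_A775dup	Phase II	PMID: 29420467	neratinib	Her2-receptor-negative breast cancer	supports	Predicted sensitive to neratinib in Her2-receptor-negative breast cancer
JAX-CKB	Y772_A775dup	Phase II	PMID: 29420467	neratinib	urinary bladder cancer and NSCLC	supports	Predicted resistant to neratinib in urinary bladder cancer and NSCLC
JAX-CKB	Y772_A775dup	Preclinical	PMID: 26545934	afatinib	lung cancer	supports	Sensitive to afatinib in lung cancer
JAX-CKB	Y772_A775dup	Preclinical	PMID: 26545934	gefitinib	lung cancer	does_not_support	No benefit to gefitinib in lung cancer
JAX-CKB	Y772_A775dup	Preclinical	PMID: 28363995	neratinib	advanced solid tumor	supports	Sensitive to neratinib in advanced solid tumor
JAX-CKB	exon 20 insertion	Clinical study	PMID: 28167203	afatinib or trastuzumab	NSCLC	supports	Predicted sensitive to afatinib or trastuzumab in NSCLC
JAX-CKB	exon 20 insertion	Clinical study	PMID: 26964772	afatinib	lung adenocarcinoma	supports	Predicted sensitive to afatinib in lung adenocarcinoma
JAX-CKB	exon 20 insertion	Phase II	PMID: 29420467	neratinib	Her2-receptor-negative breast cancer	supports	Predicted sensitive to neratinib in Her2-receptor-negative breast cancer
JAX-CKB	exon 20 insertion	Phase II	PMID: 29420467	neratinib	NSCLC	does_not_support	No benefit to neratinib in NSCLC
JAX-CKB	exon 20 insertion	Preclinical	10.1158/1538-7445.AM2016-2644	AP32788	advanced solid tumor	supports	Sensitive to AP32788 in advanced solid tumor
MMatch	Y772_A775dup	Level 1B	PMID: 22325357|PMID: 26964772	afatinib	neoplasm of lung	supports	Confers sensitivity to afatinib in patients with neoplasm of lung
MMatch	Y772_A775dup	Level 2C	PMID: 26598547	trastuzumab	neoplasm of lung	supports	Confers sensitivity to trastuzumab in patients with neoplasm of lung
MMatch	Y772_A775dup	Level 2D	PMID: 22325357	afatinib	neoplasm of breast	supports	Confers sensitivity to afatinib in patients with neoplasm of breast
MMatch	A775_G776insYVMA	Level 1A	PMID: 26559459|PMID: 22325357|PMID: 26545934	afatinib	neoplasm of lung	supports	Confers sensitivity to afatinib in patients with neoplasm of lung
MMatch	A775_G776insYVMA	Level 2C	PMID: 23610105|PMID: 26964772|PMID: 22908275	afatinib	neoplasm of breast	supports	Confers sensitivity to afatinib in patients with neoplasm of breast
MMatch	A775_G776insYVMA	Level 2D	PMID: 17311002|PMID: 22908275	neratinib	neoplasm of breast	supports	Confers sensitivity to neratinib in patients with neoplasm of breast
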