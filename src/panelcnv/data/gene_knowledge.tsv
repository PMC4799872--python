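# Cardiomyopathy panel genes with clinically significant CNVs and the
# disease-mechanism knowledge used by the rule-based classifier.
# mechanism: established mechanism of pathogenic variants in the gene
#            for cardiomyopathy (LOF, GOF, unknown)
# n_tested:  number of cohort patients whose panel covered the gene
gene	diseases	mechanism	inheritance	n_tested
EMD	DCM	LOF	XL	904
GLA	HCM	LOF	XL	1252
LAMP2	HCM,DCM	LOF	XL	1361
LMNA	DCM	LOF	AD	922
MYBPC3	HCM,DCM	LOF	AD	1379
MYOZ2	HCM	unknown	AD	1252
NEXN	HCM,DCM	unknown	AD	1361
PKP2	ARVC	LOF	AD	841
TAZ	DCM,LVNC	LOF	XL	922
TTN	DCM,HCM	LOF	AD	904
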