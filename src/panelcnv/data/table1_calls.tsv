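# Clinically significant CNVs identified in the 1425-patient
# cardiomyopathy cohort: patient demographics, called region, direction
# and clinical tier (pathogenic / likely pathogenic collapsed to P_LP).
patient_id	sex	age	diagnosis	genes	region	direction	span_kind	tier	panel
51	male	36 years	DCM	LMNA	Exon 1	loss	intragenic	P_LP	PanCardio
450	male	49 years	DCM	TTN	Exon 193-244	gain	intragenic	VUS	DCM
1060	female	39 years	DCM	LAMP2	Exon 8-9	loss	intragenic	P_LP	PanCardio
104	male	55 years	HCM	MYOZ2	Exon 2	gain	intragenic	VUS	HCM
267	female	44 years	HCM	MYBPC3	Exon 12-20	loss	intragenic	P_LP	HCM
958	male	57 years	HCM	NEXN	Whole gene	gain	whole_gene	VUS	PanCardio
1044	female	1 month	HCM	GLA,LAMP2,EMD,TAZ	X chr	gain	multi_gene	VUS	PanCardio
322	male	1 year	LVNC	PKP2	Whole gene	gain	whole_gene	VUS	PanCardio
1233	male	15 years	ARVC	PKP2	Exon 8	loss	intragenic	P_LP	PanCardio
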