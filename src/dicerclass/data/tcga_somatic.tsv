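subject_id	cohort	cancer_type	origin	chromosome	position	ref	alt	callers	zygosity	consequence	hgvs_c	hgvs_p	metasvm	cadd	revel	af_exac_nontcga	af_esp	af_1kg	kb
TCGA-UCEC-03	TCGA	UCEC	somatic	chr14	95559844	C	T		het	missense	c.5125G>A	p.Asp1709Asn							
TCGA-UCEC-03	TCGA	UCEC	somatic	chr14	95580776	C	T		het	missense	c.2810G>A	p.Arg937His							
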