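subject_id	cohort	cancer_type	origin	chromosome	position	ref	alt	callers	zygosity	consequence	hgvs_c	hgvs_p	metasvm	cadd	revel	af_exac_nontcga	af_esp	af_1kg	kb
TARGET-NBL-01	TARGET	NBL	germline	chr14	95576389	G	A	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.3178C>T	p.Arg1060Trp	Deleterious	33.0	0.4				
TARGET-WT-01	TARGET	WT	germline	chr14	95585383	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.2407G>A	p.Gly803Arg	Deleterious	21.0	0.31				
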