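subject_id	cohort	cancer_type	origin	chromosome	position	ref	alt	callers	zygosity	consequence	hgvs_c	hgvs_p	metasvm	cadd	revel	af_exac_nontcga	af_esp	af_1kg	kb
TCGA-BRCA-01	TCGA	BRCA	germline	chr14	95553150	C	A	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.5471G>T	p.Gly1824Val	Deleterious	22.4	0.41		7.7e-05		
TCGA-BLCA-01	TCGA	BLCA	germline	chr14	95574889	G	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.3479C>A	p.Ser1160Tyr	Deleterious	24.1	0.44	4.71e-05			
TCGA-BLCA-02	TCGA	BLCA	germline	chr14	95561996	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4732G>A	p.Ala1578Thr	Tolerated	33.0	0.38				
TCGA-CESC-01	TCGA	CESC	germline	chr14	95564041	A	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4406T>C	p.Leu1469Pro	Deleterious	25.6	0.52	1.89e-05		0.000399	
TCGA-CESC-02	TCGA	CESC	germline	chr14	95574889	G	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.3479C>A	p.Ser1160Tyr	Deleterious	24.1	0.44	4.71e-05			
TCGA-DLBC-01	TCGA	DLBC	germline	chr14	95598236	A	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.1583T>C	p.Ile528Thr	Deleterious	23.0	0.35	1.88e-05	0.0002		
TCGA-THCA-01	TCGA	THCA	germline	chr14	95553114	G	A	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.5507C>T	p.Pro1836Leu	Deleterious	26.2	0.49				
TCGA-READ-01	TCGA	READ	germline	chr14	95580876	C	A	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	stop_gained	c.2710G>T	p.Glu904*							
TCGA-HNSC-01	TCGA	HNSC	germline	chr14	95553117	T	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.5504A>C	p.Tyr1835Ser	Deleterious	24.8	0.46				
TCGA-HNSC-02	TCGA	HNSC	germline	chr14	95598236	A	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.1583T>C	p.Ile528Thr	Deleterious	23.0	0.35	1.88e-05	0.0002		
TCGA-HNSC-03	TCGA	HNSC	germline	chr14	95567566	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4025G>A	p.Arg1342His	Deleterious	25.1	0.43				
TCGA-LUAD-01	TCGA	LUAD	germline	chr14	95560020	A	C	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4949T>G	p.Phe1650Cys	Deleterious	34.0	0.55				
TCGA-LUAD-02	TCGA	LUAD	germline	chr14	95564006	A	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4441T>C	p.Trp1481Arg	Deleterious	32.0	0.58				
TCGA-LUAD-03	TCGA	LUAD	germline	chr14	95606262	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.602G>A	p.Arg201His	Tolerated	31.5	0.33				
TCGA-OV-01	TCGA	OV	germline	chr14	95565281	C	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4168G>C	p.Asp1390His	Tolerated	35.0	0.47				
TCGA-UCEC-01	TCGA	UCEC	germline	chr14	95553193	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.5428G>A	p.Asp1810Asn							
TCGA-UCEC-01	TCGA	UCEC	germline	chr14	95565242	C	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	splice_donor	c.4206+1G>C								
TCGA-UCEC-02	TCGA	UCEC	germline	chr14	95565260	A	G	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4189T>C	p.Trp1397Arg	Tolerated	24.9	0.82				
TCGA-UCEC-03	TCGA	UCEC	germline	chr14	95561996	C	T	FreeBayes|HaplotypeCaller|UnifiedGenotyper	het	missense	c.4732G>A	p.Ala1578Thr	Tolerated	33.0	0.38				
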