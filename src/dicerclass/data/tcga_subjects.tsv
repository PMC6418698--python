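subject_id	cancer_type	sex	age_at_diagnosis	race	vital_status
TCGA-BRCA-01	BRCA	Female	43	White	Living/disease free
TCGA-BLCA-01	BLCA	Female	82	Asian	Living/disease free
TCGA-BLCA-02	BLCA	Male	70	White	Living/recurred/progressed
TCGA-CESC-01	CESC	Female	62	White	Living/disease free
TCGA-CESC-02	CESC	Female	72	Asian	Living/disease free
TCGA-DLBC-01	DLBC	Male	36	White	Living/disease free
TCGA-THCA-01	THCA	Female	64		Living/disease free
TCGA-READ-01	READ	Female	62		Living/disease free
TCGA-HNSC-01	HNSC	Male	61	White	Living/disease free
TCGA-HNSC-02	HNSC	Male	48	African American	Living/disease free
TCGA-HNSC-03	HNSC	Female	80	White	Deceased
TCGA-LUAD-01	LUAD	Female	60	White	Living/recurred/progressed
TCGA-LUAD-02	LUAD	Male	67	White	Living/disease free
TCGA-LUAD-03	LUAD	Male	70	White	Deceased
TCGA-OV-01	OV	Female	39	White	Deceased/recurred/progressed
TCGA-UCEC-01	UCEC	Female	57	African American	Living/disease free
TCGA-UCEC-02	UCEC	Female	60	White	Living/disease free
TCGA-UCEC-03	UCEC	Female	69	White	Living/disease free
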