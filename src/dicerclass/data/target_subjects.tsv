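subject_id	cancer_type	sex	age_at_diagnosis	race	vital_status
TARGET-NBL-01	NBL	Male	4		Living
TARGET-WT-01	WT	Female	3		Living
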