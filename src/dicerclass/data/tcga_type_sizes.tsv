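cancer_type	n
BRCA	966
BLCA	394
CESC	300
DLBC	44
THCA	431
READ	153
HNSC	509
LUAD	441
OV	415
UCEC	524
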