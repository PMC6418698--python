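cancer_type	n
NBL	142
WT	33
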