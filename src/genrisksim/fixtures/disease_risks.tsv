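# Population disease risks (prior probability of disease) used in the
# replication of published genetic prediction studies.
disease	d
type_2_diabetes	0.20
prostate_cancer	0.15
type_1_diabetes	0.002
amd	0.065
colorectal_cancer	0.048
crohn_disease	0.002
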