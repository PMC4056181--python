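# SYNTHETIC stand-in risk-allele frequencies for the 18-SNP type 2 diabetes
# panels.  The exact frequencies used by the original replication are not
# shipped; these are typical European-ancestry risk-allele frequencies for
# the same SNPs, chosen once from the genetic-epidemiology literature.
# Results computed with them are approximations of the original conditions.
snp_id	raf
rs2641348	0.10
rs4607103	0.76
rs12779790	0.18
rs10946398	0.32
rs10811661	0.83
rs564398	0.58
rs8050136	0.40
rs1111875	0.56
rs4402960	0.32
rs864745	0.50
rs5219	0.37
rs1801282	0.85
rs13266634	0.75
rs757210	0.38
rs7903146	0.30
rs7578597	0.90
rs7961581	0.27
rs10010131	0.60
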