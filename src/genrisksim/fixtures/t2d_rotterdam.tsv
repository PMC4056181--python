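# 18-SNP type 2 diabetes panel (Rotterdam prediction study): per-allele odds
# ratios with 95% CIs as reported in the cited genome-wide association studies.
# Differs from the GoDARTS panel at rs5219, rs757210 and rs7903146, where the
# two studies cited different GWASs.
# No raf column: risk-allele frequencies are user-supplied (see t2d_raf_synthetic.tsv
# for a synthetic stand-in set).
snp_id	or_allele	ci_low	ci_high
rs2641348	1.10	1.06	1.15
rs4607103	1.09	1.06	1.12
rs12779790	1.11	1.07	1.14
rs10946398	1.12	1.08	1.16
rs10811661	1.20	1.14	1.25
rs564398	1.12	1.07	1.17
rs8050136	1.15	1.09	1.22
rs1111875	1.13	1.08	1.17
rs4402960	1.17	1.10	1.25
rs864745	1.10	1.07	1.13
rs5219	1.14	1.10	1.19
rs1801282	1.14	1.08	1.20
rs13266634	1.12	1.07	1.16
rs757210	1.22	1.15	1.30
rs7903146	1.38	1.31	1.46
rs7578597	1.15	1.10	1.20
rs7961581	1.09	1.06	1.12
rs10010131	1.11	1.07	1.16
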