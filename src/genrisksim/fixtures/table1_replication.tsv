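# Published AUC values of genetic prediction studies alongside the AUC
# estimates obtained in simulated data, by risk-model type.
disease	study_id	model_type	published_auc	simulated_auc
crohn_disease	Peter_2009	unweighted	0.70	0.67
prostate_cancer	Johansson_2012	unweighted	0.64	0.67
type_1_diabetes	Yamashita_2011	unweighted	0.65	0.64
type_2_diabetes	Lin_2009	unweighted	0.57	0.59
type_2_diabetes	Qi_2010	unweighted	0.62	0.60
type_2_diabetes	VanHoek_2008	unweighted	0.56	0.60
type_2_diabetes	Meigs_2008	unweighted	0.58	0.59
type_2_diabetes	Wang_2010	unweighted	0.55	0.60
type_2_diabetes	Talmud_2010	unweighted	0.54	0.60
prostate_cancer	Sun_2011	weighted	0.62	0.66
prostate_cancer	Kader_2012	weighted	0.59	0.67
type_2_diabetes	Lin_2009	weighted	0.59	0.60
type_2_diabetes	Talmud_2010	weighted	0.55	0.61
amd	Scholl_2007	logistic	0.73	0.69
amd	Hecker_2010	logistic	0.77	0.76
amd	Grassmann_2012	logistic	0.82	0.78
colorectal_cancer	Dunlop_2012	logistic	0.57	0.60
colorectal_cancer	Lubbe_2012	logistic	0.58	0.60
crohn_disease	Peter_2009	logistic	0.71	0.68
prostate_cancer	Aly_2011	logistic	0.67	0.69
prostate_cancer	Helfand_2008	logistic	0.61	0.62
type_2_diabetes	Weedon_2006	logistic	0.58	0.59
type_2_diabetes	Vaxillaire_2008	logistic	0.56	0.58
type_2_diabetes	Hu_2009	logistic	0.62	0.61
type_2_diabetes	Miyake_2009	logistic	0.63	0.63
type_2_diabetes	FontaineBisson_2010	logistic	0.59	0.61
type_2_diabetes	VanHoek_2008	logistic	0.60	0.61
type_2_diabetes	Lango_2008	logistic	0.60	0.61
type_2_diabetes	Sparso_2009	logistic	0.60	0.61
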