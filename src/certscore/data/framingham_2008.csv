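sex,term,value
F,ln_age,2.32888
F,ln_tc,1.20904
F,ln_hdl,-0.70833
F,ln_sbp_untreated,2.76157
F,ln_sbp_treated,2.82263
F,smoker,0.52873
F,diabetes,0.69154
F,baseline_survival_10y,0.95012
F,mean_linear_predictor,26.1931
M,ln_age,3.06117
M,ln_tc,1.12370
M,ln_hdl,-0.93263
M,ln_sbp_untreated,1.93303
M,ln_sbp_treated,1.99881
M,smoker,0.65451
M,diabetes,0.57367
M,baseline_survival_10y,0.88936
M,mean_linear_predictor,23.9802
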