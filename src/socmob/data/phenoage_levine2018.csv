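# PhenoAge blood-chemistry mortality-score coefficients, transcribed from the
# published parameterization (Levine et al. 2018, NHANES III training data).
# Units: albumin g/L; creatinine umol/L; glucose mmol/L; crp_log = ln(CRP mg/dL);
# lymphocyte_pct %; mcv fL; rdw %; alkaline_phosphatase U/L; wbc 10^9 cells/L;
# age years. Gompertz mortality model over a 120-month horizon; calibration
# constants map 10-year mortality risk to the reference age scale.
term,value
intercept,-19.9067
albumin,-0.0336
creatinine,0.0095
glucose,0.1953
crp_log,0.0954
lymphocyte_pct,-0.0120
mcv,0.0268
rdw,0.3306
alkaline_phosphatase,0.00188
wbc,0.0554
age,0.0804
gompertz_gamma,0.0076927
horizon_months,120
calib_age_anchor,141.50225
calib_risk_scale,0.00553
calib_age_rate,0.090165
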