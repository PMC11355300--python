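characteristic,mean,sd
age_years,31.62,5.28
gestational_age_weeks,40.16,1.02
gestational_age_days,283.09,7.15
bmi,27.52,2.95
neonatal_weight_g,3926.68,309.66
apgar1,6.65,1.22
apgar5,8.74,1.12
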