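n_predictions,patient_id,asynclitism_type,actual_outcome,zone_ad,zone_aop,zone_mla,zone_hsd,predicted_svm,predicted_rf,predicted_mlp
3,3,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,17,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,21,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,23,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,30,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,35,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,37,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,40,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,ICD,NOICD,NOICD
1,45,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,48,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,87,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,105,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,109,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,125,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,6,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,14,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,19,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,41,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,62,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,75,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,95,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,103,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,134,anterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,1,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,5,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,27,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,49,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,56,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,80,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,108,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
3,130,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,16,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,31,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,54,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,81,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
2,89,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,90,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
1,132,posterior,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
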