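n_predictions,patient_id,asynclitism_type,actual_outcome,zone_ad,zone_aop,zone_mla,zone_hsd,predicted_svm,predicted_rf,predicted_mlp
2,26,anterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,29,anterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,110,anterior,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
2,115,anterior,NOICD,RED,RED,RED,GREEN,ICD,NOICD,ICD
1,127,anterior,ICD,YELLOW,RED,GREEN,RED,ICD,ICD,ICD
2,127,anterior,ICD,YELLOW,RED,GREEN,RED,ICD,ICD,NOICD
1,12,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,28,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,33,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
3,39,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,42,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,44,posterior,ICD,GREEN,RED,YELLOW,RED,ICD,ICD,ICD
1,50,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,51,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,63,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,77,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,96,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
3,7,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,20,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,24,posterior,NOICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,43,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,46,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
2,118,posterior,ICD,GREEN,RED,RED,RED,ICD,ICD,ICD
1,59,posterior,ICD,RED,RED,GREEN,RED,ICD,ICD,ICD
1,88,posterior,ICD,RED,RED,GREEN,RED,ICD,ICD,ICD
1,99,posterior,ICD,RED,GREEN,RED,RED,ICD,ICD,ICD
2,100,posterior,NOICD,RED,RED,RED,GREEN,ICD,ICD,ICD
1,126,posterior,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
1,135,posterior,ICD,RED,RED,RED,GREEN,ICD,ICD,NOICD
1,124,posterior,ICD,YELLOW,RED,GREEN,RED,ICD,ICD,ICD
2,38,posterior,ICD,YELLOW,RED,GREEN,RED,ICD,ICD,NOICD
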