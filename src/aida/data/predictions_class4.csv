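n_predictions,patient_id,asynclitism_type,actual_outcome,zone_ad,zone_aop,zone_mla,zone_hsd,predicted_svm,predicted_rf,predicted_mlp
1,74,anterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
2,83,anterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,2,anterior,ICD,YELLOW,RED,YELLOW,RED,ICD,ICD,ICD
3,4,anterior,ICD,YELLOW,RED,RED,RED,ICD,ICD,ICD
4,22,anterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,67,anterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,121,anterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,102,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
3,60,posterior,ICD,YELLOW,RED,RED,RED,ICD,ICD,ICD
2,69,posterior,ICD,YELLOW,RED,RED,RED,ICD,ICD,ICD
1,84,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,85,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,93,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
3,117,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
3,18,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,71,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
1,78,posterior,ICD,RED,RED,RED,RED,ICD,ICD,NOICD
1,114,posterior,ICD,RED,RED,RED,RED,ICD,ICD,ICD
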