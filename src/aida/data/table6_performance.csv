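aida_class,algorithm,accuracy,ppv,npv,recall,specificity,f1,tp,fp,fn,tn
0,RF,1,NA,1,NA,1,NA,0,0,0,68
0,SVM,0.9853,0.00,1,NA,0.9853,NA,0,1,0,67
0,MLP,1,NA,1,NA,1,NA,0,0,0,68
3,RF,0.920,0.9167,1,1,0.3333,0.9565,44,4,0,2
3,SVM,0.880,0.880,NA,1,0.00,0.9362,44,6,0,0
3,MLP,0.780,0.8667,0.00,0.8864,0.00,0.8764,39,6,5,0
4,RF,1,1,NA,1,NA,1,31,0,0,0
4,SVM,1,1,NA,1,NA,1,31,0,0,0
4,MLP,0.9677,1,0.00,0.9677,NA,0.9836,30,0,1,0
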