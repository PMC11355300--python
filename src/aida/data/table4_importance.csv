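algorithm,ad_rank,ranking
MLP,4,aop_deg>hsd_mm>mla_deg>ad_mm
RF,3,mla_deg>hsd_mm>ad_mm>aop_deg
SVM,2,hsd_mm>ad_mm>mla_deg>aop_deg
XGBoost,2,hsd_mm>ad_mm>mla_deg
LR,4,hsd_mm>mla_deg>aop_deg>ad_mm
DT,3,mla_deg>aop_deg>ad_mm>hsd_mm
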