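var1,var2,pc,strength,p
apgar1,apgar5,0.8,very strong,8.42e-32
aop_deg,ad_mm,0.36,weak,0.00002
hsd_mm,ad_mm,0.18,very weak,0.03
mla_deg,ad_mm,0.14,very weak,0.09
apgar1,ad_mm,-0.2,weak,0.02
apgar5,ad_mm,-0.19,very weak,0.02
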