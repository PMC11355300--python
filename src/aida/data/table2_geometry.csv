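parameter,min,max,mean,sd
hsd_mm,10,51,21.47,9.265
ad_mm,4,95,60.18,18.866
mla_deg,26,90,62.59,14.986
aop_deg,72,192,122.75,27.454
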