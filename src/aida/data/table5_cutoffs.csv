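pair,feature,direction,threshold
AD-AoP,ad_mm,>=,67
AD-AoP,aop_deg,>=,144.5
AD-AoP,aop_deg,<,101.5
AD-HSD,ad_mm,>=,70.5
AD-HSD,hsd_mm,>=,19.5
AD-MLA,ad_mm,>=,65.5
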