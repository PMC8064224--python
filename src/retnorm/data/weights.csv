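group,age_months,mean_g,sd_g,printed_p
WT,1,14.84,2.68,0.86
WT,2,22.65,1.69,0.39
WT,3,25.29,1.92,0.47
WT,4,27.02,2.07,0.36
3xTg-AD,1,14.94,2.66,0.86
3xTg-AD,2,22.33,2.31,0.39
3xTg-AD,3,25.57,2.27,0.47
3xTg-AD,4,27.41,2.06,0.36
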