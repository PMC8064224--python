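group,eye,age_months,layer,region,mean_um,sd_um,n
WT,combined,1,RNFL-GCL,whole,12.90,0.72,104
WT,combined,1,IPL,whole,51.55,2.04,104
WT,combined,1,INL,whole,25.57,1.02,104
WT,combined,1,OPL,whole,15.22,0.30,104
WT,combined,1,ONL,whole,62.13,1.17,104
WT,combined,1,IS,whole,10.79,0.53,104
WT,combined,1,OS,whole,11.61,0.40,104
WT,combined,1,RPE,whole,20.93,1.45,104
WT,combined,1,TRT,whole,210.06,3.09,104
WT,combined,2,RNFL-GCL,whole,13.10,0.89,102
WT,combined,2,IPL,whole,48.04,2.31,102
WT,combined,2,INL,whole,21.93,0.86,102
WT,combined,2,OPL,whole,15.13,0.31,102
WT,combined,2,ONL,whole,60.64,1.38,102
WT,combined,2,IS,whole,11.07,0.57,102
WT,combined,2,OS,whole,11.36,0.47,102
WT,combined,2,RPE,whole,22.89,1.04,102
WT,combined,2,TRT,whole,202.90,3.29,102
WT,combined,3,RNFL-GCL,whole,13.44,0.93,85
WT,combined,3,IPL,whole,47.52,3.19,85
WT,combined,3,INL,whole,21.45,0.89,85
WT,combined,3,OPL,whole,15.12,0.21,85
WT,combined,3,ONL,whole,60.64,1.19,85
WT,combined,3,IS,whole,11.04,0.42,85
WT,combined,3,OS,whole,11.19,0.33,85
WT,combined,3,RPE,whole,23.24,1.23,85
WT,combined,3,TRT,whole,203.34,3.59,85
WT,combined,4,RNFL-GCL,whole,13.48,0.72,103
WT,combined,4,IPL,whole,47.23,1.92,103
WT,combined,4,INL,whole,20.62,0.61,103
WT,combined,4,OPL,whole,15.11,0.23,103
WT,combined,4,ONL,whole,60.15,0.98,103
WT,combined,4,IS,whole,11.21,0.42,103
WT,combined,4,OS,whole,11.14,0.39,103
WT,combined,4,RPE,whole,23.47,0.90,103
WT,combined,4,TRT,whole,200.69,2.40,103
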