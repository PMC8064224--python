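group,eye,age_months,layer,region,mean_um,sd_um,n
3xTg-AD,combined,1,RNFL-GCL,whole,13.15,0.79,94
3xTg-AD,combined,1,IPL,whole,47.92,2.45,94
3xTg-AD,combined,1,INL,whole,22.41,0.99,94
3xTg-AD,combined,1,OPL,whole,14.90,0.31,94
3xTg-AD,combined,1,ONL,whole,62.09,1.58,94
3xTg-AD,combined,1,IS,whole,10.18,0.36,94
3xTg-AD,combined,1,OS,whole,11.29,0.38,94
3xTg-AD,combined,1,RPE,whole,19.42,0.82,94
3xTg-AD,combined,1,TRT,whole,200.54,3.83,94
3xTg-AD,combined,2,RNFL-GCL,whole,13.69,0.87,83
3xTg-AD,combined,2,IPL,whole,45.59,2.39,83
3xTg-AD,combined,2,INL,whole,19.63,0.85,83
3xTg-AD,combined,2,OPL,whole,14.81,0.26,83
3xTg-AD,combined,2,ONL,whole,60.57,1.80,83
3xTg-AD,combined,2,IS,whole,10.61,0.38,83
3xTg-AD,combined,2,OS,whole,11.34,0.50,83
3xTg-AD,combined,2,RPE,whole,21.46,1.06,83
3xTg-AD,combined,2,TRT,whole,196.77,3.70,83
3xTg-AD,combined,3,RNFL-GCL,whole,13.95,0.85,88
3xTg-AD,combined,3,IPL,whole,45.79,2.30,88
3xTg-AD,combined,3,INL,whole,19.50,0.62,88
3xTg-AD,combined,3,OPL,whole,14.92,0.23,88
3xTg-AD,combined,3,ONL,whole,60.59,1.64,88
3xTg-AD,combined,3,IS,whole,10.80,0.40,88
3xTg-AD,combined,3,OS,whole,11.34,0.40,88
3xTg-AD,combined,3,RPE,whole,21.90,1.01,88
3xTg-AD,combined,3,TRT,whole,197.68,3.18,88
3xTg-AD,combined,4,RNFL-GCL,whole,14.03,0.72,84
3xTg-AD,combined,4,IPL,whole,45.86,2.72,84
3xTg-AD,combined,4,INL,whole,18.96,0.73,84
3xTg-AD,combined,4,OPL,whole,14.89,0.27,84
3xTg-AD,combined,4,ONL,whole,59.86,1.84,84
3xTg-AD,combined,4,IS,whole,10.97,0.36,84
3xTg-AD,combined,4,OS,whole,11.43,0.41,84
3xTg-AD,combined,4,RPE,whole,22.29,1.02,84
3xTg-AD,combined,4,TRT,whole,196.16,3.14,84
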