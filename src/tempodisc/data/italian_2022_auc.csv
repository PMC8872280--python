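index_type,sex,education_level,percentile_level,threshold
auc,F,1,5,0.02
auc,F,1,10,0.04
auc,F,1,25,0.11
auc,F,1,50,0.26
auc,F,1,75,0.38
auc,F,1,85,0.46
auc,F,1,90,0.66
auc,F,1,95,0.97
auc,F,2,5,0.02
auc,F,2,10,0.03
auc,F,2,25,0.20
auc,F,2,50,0.29
auc,F,2,75,0.52
auc,F,2,85,0.72
auc,F,2,90,0.82
auc,F,2,95,0.87
auc,F,3,5,0.04
auc,F,3,10,0.12
auc,F,3,25,0.29
auc,F,3,50,0.40
auc,F,3,75,0.66
auc,F,3,85,0.77
auc,F,3,90,0.79
auc,F,3,95,0.89
auc,M,1,5,0.02
auc,M,1,10,0.18
auc,M,1,25,0.26
auc,M,1,50,0.37
auc,M,1,75,0.59
auc,M,1,85,0.66
auc,M,1,90,0.71
auc,M,1,95,0.79
auc,M,2,5,0.08
auc,M,2,10,0.14
auc,M,2,25,0.30
auc,M,2,50,0.41
auc,M,2,75,0.57
auc,M,2,85,0.69
auc,M,2,90,0.74
auc,M,2,95,0.79
auc,M,3,5,0.08
auc,M,3,10,0.16
auc,M,3,25,0.25
auc,M,3,50,0.41
auc,M,3,75,0.70
auc,M,3,85,0.85
auc,M,3,90,0.89
auc,M,3,95,0.91
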