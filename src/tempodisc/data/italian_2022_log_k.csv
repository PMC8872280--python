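index_type,sex,education_level,percentile_level,threshold
log_k_hyperbolic,F,1,5,-6.35
log_k_hyperbolic,F,1,10,-5.06
log_k_hyperbolic,F,1,25,-4.21
log_k_hyperbolic,F,1,50,-2.70
log_k_hyperbolic,F,1,75,-0.67
log_k_hyperbolic,F,1,85,0.35
log_k_hyperbolic,F,1,90,0.97
log_k_hyperbolic,F,1,95,2.38
log_k_hyperbolic,F,2,5,-7.57
log_k_hyperbolic,F,2,10,-6.62
log_k_hyperbolic,F,2,25,-4.80
log_k_hyperbolic,F,2,50,-3.73
log_k_hyperbolic,F,2,75,-2.19
log_k_hyperbolic,F,2,85,-1.03
log_k_hyperbolic,F,2,90,-0.18
log_k_hyperbolic,F,2,95,2.73
log_k_hyperbolic,F,3,5,-7.51
log_k_hyperbolic,F,3,10,-6.42
log_k_hyperbolic,F,3,25,-5.55
log_k_hyperbolic,F,3,50,-4.35
log_k_hyperbolic,F,3,75,-2.94
log_k_hyperbolic,F,3,85,-2.38
log_k_hyperbolic,F,3,90,-2.08
log_k_hyperbolic,F,3,95,-1.00
log_k_hyperbolic,M,1,5,-6.51
log_k_hyperbolic,M,1,10,-6.03
log_k_hyperbolic,M,1,25,-5.08
log_k_hyperbolic,M,1,50,-3.94
log_k_hyperbolic,M,1,75,-3.20
log_k_hyperbolic,M,1,85,-2.73
log_k_hyperbolic,M,1,90,-1.75
log_k_hyperbolic,M,1,95,0.69
log_k_hyperbolic,M,2,5,-6.55
log_k_hyperbolic,M,2,10,-6.16
log_k_hyperbolic,M,2,25,-5.12
log_k_hyperbolic,M,2,50,-4.10
log_k_hyperbolic,M,2,75,-3.17
log_k_hyperbolic,M,2,85,-2.20
log_k_hyperbolic,M,2,90,-1.42
log_k_hyperbolic,M,2,95,-0.42
log_k_hyperbolic,M,3,5,-7.59
log_k_hyperbolic,M,3,10,-7.32
log_k_hyperbolic,M,3,25,-6.00
log_k_hyperbolic,M,3,50,-4.13
log_k_hyperbolic,M,3,75,-3.10
log_k_hyperbolic,M,3,85,-2.84
log_k_hyperbolic,M,3,90,-2.37
log_k_hyperbolic,M,3,95,-1.91
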