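metric,P1,P2,P3,P4,P5,P6,P7,P8
planning_time_s,162,70,117,88,64,37,71,110
execution_time_s,87,39,13,19,17,35,26,24
n_xrays,8,8,8,8,8,8,8,8
dose_cgy_cm2,1.27,1.3,1.23,1.26,1.18,1.25,1.18,1.29
abduction_error_deg,2.1,1,1.1,1.3,2.9,0.1,0.4,3.7
anteversion_error_deg,1.1,0.6,2.7,1.4,2.1,0.4,0.3,3.1
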