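metric,P1,P2,P3,P4,P5,P6,P7,P8
planning_time_s,125,40,39,58,79,22,67,44
execution_time_s,83,74,58,46,66,67,63,79
n_xrays,2,2,2,2,2,2,2,2
dose_cgy_cm2,0.28,0.21,0.19,0.27,0.26,0.28,0.27,0.28
wire_error_mm,8.23,5.71,9.02,3.26,6.94,1.13,1.59,2.23
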