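metric,Q1,Q2,Q3,Q4,Q5,Q6,Q7
time_s,937,686,617,464,636,388,432
n_xrays,80,47,44,33,32,21,29
dose_cgy_cm2,7.68,1.73,3.54,4.38,5.62,2.69,5.38
wire_error_mm,3.08,7.88,11.43,3.01,1.87,2.27,2.72
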