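table,metric,statistic,published,note
kwire_ar,planning_time_s,mean,59.25,
kwire_ar,planning_time_s,sd_sample,32.02,
kwire_ar,execution_time_s,mean,52,published execution mean disagrees with the per-participant row (mean 67.0); the published combined time 111.25 is consistent with 52
kwire_ar,execution_time_s,sd_sample,24.23,SD of the published summary; the per-participant row gives 11.9
kwire_ar,n_xrays,mean,2,
kwire_ar,n_xrays,sd_sample,0,
kwire_ar,dose_cgy_cm2,mean,0.255,
kwire_ar,dose_cgy_cm2,sd_sample,0.04,
kwire_ar,wire_error_mm,mean,4.76,
kwire_ar,wire_error_mm,sd_population,2.91,prose mean-plus-minus-SD form uses the population SD
kwire_ar,wire_error_mm,sd_sample,3.11,tabulated parenthesised SD uses the sample SD
kwire_ar,wire_error_mm,ci95_low,2.60,z-based 95 percent CI with sample SD
kwire_ar,wire_error_mm,ci95_high,6.92,z-based 95 percent CI with sample SD
tha_ar,planning_time_s,mean,89.88,
tha_ar,planning_time_s,sd_sample,38.85,
tha_ar,execution_time_s,mean,32.5,
tha_ar,execution_time_s,sd_sample,23.71,
tha_ar,n_xrays,mean,8,
tha_ar,n_xrays,sd_sample,0,
tha_ar,dose_cgy_cm2,mean,1.25,
tha_ar,dose_cgy_cm2,sd_sample,1.25,published SD equals the mean; the per-participant row gives 0.046 - likely a transcription slip
tha_ar,abduction_error_deg,mean,1.57,
tha_ar,abduction_error_deg,sd_population,1.16,
tha_ar,abduction_error_deg,sd_sample,1.24,
tha_ar,abduction_error_deg,ci95_low,0.72,
tha_ar,abduction_error_deg,ci95_high,2.44,
tha_ar,anteversion_error_deg,mean,1.46,
tha_ar,anteversion_error_deg,sd_population,1.00,
tha_ar,anteversion_error_deg,sd_sample,1.07,
tha_ar,anteversion_error_deg,ci95_low,0.72,
tha_ar,anteversion_error_deg,ci95_high,2.20,
kwire_sop,time_s,mean,594.3,
kwire_sop,time_s,sd_sample,188.0,recomputed sample SD is 188.8; published rounds low
kwire_sop,n_xrays,mean,40.86,
kwire_sop,n_xrays,sd_sample,19.38,
kwire_sop,dose_cgy_cm2,mean,4.43,
kwire_sop,dose_cgy_cm2,sd_sample,2.00,
kwire_sop,wire_error_mm,mean,4.61,
kwire_sop,wire_error_mm,sd_sample,3.62,
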