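compound,max_flux_mean,max_flux_sd,kp_cm_per_h,percent_median,percent_ci_low,percent_ci_high,detected
pHBA,12.68,4.08,0.012,0.997,0,1.22,True
MP,76.23,26.60,0.305,9.148,4.94,19.70,True
EP,2.35,0.71,9.4e-4,0.110,0,0.11,True
PrP,,,,,,,False
iPrP,,,,,,,False
BuP,,,,,,,False
iBuP,,,,,,,False
BzP,,,,,,,False
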