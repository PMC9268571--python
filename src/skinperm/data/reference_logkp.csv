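compound,log_kp_exp_cm_per_s,log_kp_insilico_cm_per_s
pHBA,-5.48,-6.02
MP,-4.07,-5.84
EP,-6.58,-5.56
PrP,,-5.24
iPrP,,-5.40
BuP,,-4.95
iBuP,,-5.05
BzP,,-4.93
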