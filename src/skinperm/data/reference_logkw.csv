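compound,log_kw_mg,log_kw_dd2
pHBA,-0.955,-1.054
MP,0.615,1.306
EP,0.956,1.751
PrP,1.339,2.267
iPrP,1.227,1.914
BuP,1.818,2.812
iBuP,1.708,2.448
BzP,2.292,2.735
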