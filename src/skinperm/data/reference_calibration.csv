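compound,slope,intercept,r2,range_low,range_high,rt_min,mobile_phase
pHBA,43879,11792,0.9992,20,40,6.1,40:60
MP,402.09,1120.1,0.9988,5,40,8.3,50:50
EP,3503.5,1344.3,0.9861,5,40,10.9,50:50
PrP,1059.8,1647.2,0.9973,2.5,20,15.7,50:50
iPrP,795.67,2048.8,0.9975,2.5,20,10.6,60:40
BuP,2275.3,2863.3,0.9256,2.5,20,14.5,60:40
iBuP,1271.4,1831.0,0.9984,2.5,20,23.0,50:50
BzP,723.07,2675.1,0.9976,2.5,20,14.5,60:40
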