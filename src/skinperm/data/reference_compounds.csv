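name,mw_g_per_mol,logp,solubility_ug_per_ml,pka,annotation
pHBA,138.12,1.58,5000,4.01,
MP,152.16,1.96,2500,,
EP,166.18,2.47,885,,
PrP,180.21,1.96,500,,suspected logP transcription duplicate of MP; in-silico column implies logP ~3.04
iPrP,180.21,1.96,500,,suspected logP transcription duplicate of MP; in-silico column implies logP ~2.82
BuP,194.23,3.57,207,,
iBuP,194.23,3.57,207,,printed logP duplicates BuP; in-silico column implies logP ~3.43
BzP,228.25,3.56,92,,in-silico column implies logP ~3.89
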