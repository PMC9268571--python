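"""Potts-Guy in-silico log Kp next to the experimental values.

Predicts log10 Kp (cm/s) for all eight benchmark compounds from log P
and molecular weight, and prints the experimental column (measured Kp
in cm/h converted to log cm/s) beside it. 'nd' marks compounds never
detected in the receptor fluid: the QSPR predicts permeability for them
anyway — the disagreement is the point of the comparison.
"""

from skinperm import kp_log_cm_per_s, potts_guy_logkp
from skinperm.datasets import load_reference_compounds, load_reference_permeation

perm = {s.compound: s for s in load_reference_permeation()}
print(f"{'compound':<8} {'logP':>5} {'MW':>7}   {'pred':>6} {'experimental':>12}")
for c in load_reference_compounds():
    pred = potts_guy_logkp(c.logp, c.mw)
    s = perm[c.name]
    exp = f"{kp_log_cm_per_s(s.kp_cm_per_h):.2f}" if s.detected else "nd"
    print(f"{c.name:<8} {c.logp:>5.2f} {c.mw:>7.2f}   {pred:>6.2f} {exp:>12}")
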