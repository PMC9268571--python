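"""Fit an HPLC calibration line and back-calculate a concentration.

Five standards with slight detector scatter give a calibration curve
with its ICH-style detection limits (3.3 sigma/slope, 10 sigma/slope);
an unknown response is then inverted to a concentration, with censoring
when it falls under the LOD.
"""

import numpy as np

from skinperm import CalibrationLevel, fit_calibration, inverse_predict

rng = np.random.default_rng(1)
conc = np.array([2.5, 5.0, 10.0, 20.0, 40.0])  # ug/mL
resp = 402.09 * conc + 1120.1 + rng.normal(0, 150, conc.size)

curve = fit_calibration(
    [CalibrationLevel(c, r) for c, r in zip(conc, resp)],
    valid_range=(2.5, 40.0), compound="MP",
)
print(f"slope {curve.slope:.1f}, intercept {curve.intercept:.0f}, r2 {curve.r2:.4f}")
print(f"LOD {curve.lod:.3f} ug/mL, LOQ {curve.loq:.3f} ug/mL")

for response in (1500.0, 6000.0):
    c, censored, extrapolated = inverse_predict(curve, response)
    tag = " (censored < LOD)" if censored else ""
    print(f"response {response:>6.0f} -> {c:.3f} ug/mL{tag}")
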