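"""Polycratic log kw extrapolation and the two-phase comparison.

First recovers a known log kw from simulated isocratic retention times
(linear solvent-strength law, three acetonitrile fractions), then
regresses the packaged two-phase reference values against each other:
the r² near 0.9 over the seven esters says the two stationary phases
rank phospholipophilicity the same way, with the ionized acid (pHBA)
the documented outlier.
"""

from skinperm import cross_phase_regression, extrapolate_logkw, simulate_retention
from skinperm.datasets import load_reference_logkw

ms = simulate_retention(
    log_kw=2.0, slope=-5.0, t_0=2.0, phi_list=[0.10, 0.20, 0.30],
    noise_sd=0.01, seed=42,
)
fit = extrapolate_logkw(ms)
print(f"recovered log kw : {fit.log_kw:.3f} (truth 2.000), "
      f"slope {fit.slope:.2f}, r2 {fit.r2:.4f}")

pairs = load_reference_logkw()
slope, intercept, r2, n = cross_phase_regression(pairs, exclude={"pHBA"})
print(f"phase comparison : DD2 = {slope:.3f} * MG + {intercept:.3f}, "
      f"r2 = {r2:.3f} (n = {n}, esters only)")
_, _, r2_all, n_all = cross_phase_regression(pairs)
print(f"with the acid    : r2 = {r2_all:.3f} (n = {n_all})")
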