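# Methods

## Scope and data model

The package analyses membrane-barrier passage of small molecules by
three routes — Franz diffusion cells (FDC), immobilized-artificial-
membrane (IAM) chromatography, and the Potts–Guy QSPR — and compares
them. The benchmark dataset is p-hydroxybenzoic acid and seven paraben
esters; it ships as summary-level CSV tables (physicochemical
properties, calibration lines, permeation summaries, two-phase log k_w,
experimental and in-silico log Kp). The raw chromatographic and
receptor-fluid data behind those summaries were never published, so the
summaries are fixtures for comparison and inverse prediction, not
quantities the package can re-derive; pipeline correctness is instead
demonstrated on simulated data with known ground truth.

## Franz-cell pipeline

**Sampling correction.** Each scheduled aliquot (volume V_s) is
withdrawn and replaced with fresh medium, diluting the receptor. The
cumulative amount uses the standard fixed-volume bookkeeping
Q_n = V_r·C_n + V_s·Σ_{i<n} C_i. The simulator generates measured
concentrations by the exact inverse recursion, so at zero noise the
correction reconstructs the true Q(t) to machine precision — this is a
tested invariant, not an approximation.

**Flux and Kp.** The printed flux relation in the benchmark's source is
dimensionally ambiguous as typeset; it is implemented as
J = ΔQ/(A·Δt), consistent with its prose definition and with µg/cm²/h
units. "Maximum flux" defaults to the maximum per-interval flux (the
series is anchored at Q = 0, t = 0, so the first half-hour sample forms
an ordinary interval); this definition can express an early transient
maximum, which the benchmark compounds show. A `flux_mode="origin"`
switch offers max over Q_n/(A·t_n) instead. Kp = J_max/Cd matches how
the benchmark pairs its flux and Kp columns; note that the maximum of
noisy interval fluxes is an extreme statistic and is biased high under
measurement noise, so a steady-state estimate (OLS slope of Q(t) over a
late window, default 2–6 h, divided by A) is computed alongside and is
the estimator validated against simulator ground truth.

**Units.** Concentrations in µg/mL (≡ µg/cm³ ≡ mg/L), amounts in µg,
times in h, areas in cm², Kp in cm/h with the conventional
log10(cm/s) = log10(Kp/3600) transform for reporting.

**Censoring and nd.** Concentrations below the assay LOD are censored:
they contribute zero mass with the flag propagated. A cell with every
time point censored is "not detected"; nd propagates as NaN plus a
`detected` flag — never as zero — into replicate aggregation and
reports (printed as the literal `nd`).

**Aggregation.** Replicates (the benchmark used triplicates) are
summarised as mean ± SD (n−1) of maximum flux, Kp from the mean maximum
flux, and median percent absorption with a 95% percentile-bootstrap CI
(10,000 resamples, seeded `numpy.random.default_rng`; lower bound
floored at 0). The CI method for the benchmark's printed intervals is
unstated; percentile bootstrap is the package's choice.

**Mass balance.** A cumulative amount exceeding the applied dose, or
percent absorption above 100%, raises a warning and the percent is
capped; the analysis is not aborted because such violations are
informative about calibration or bookkeeping errors.

## Calibration

Unweighted OLS of response on concentration (the benchmark reports a
single slope/intercept/r² per compound with no weighting mention);
r² is the squared Pearson correlation; residual SD uses the n−2
denominator. LOD = 3.3·σ/|slope| and LOQ = 10·σ/|slope| follow the ICH
convention for HPLC-UV methods — the benchmark reports LODs without a
formula, so this standard definition is adopted. Inverse prediction
floors negative back-calculations at zero (physical quantity), censors
below the LOD, and flags values above the calibrated range as
extrapolated rather than rejecting them. Responses are assumed
blank-corrected; no blank-subtraction stage exists.

## IAM chromatography

The polycratic model is the linear solvent-strength law
log10 k = log k_w − S·φ, conventional over the narrow acetonitrile
range used (φ = 0.10–0.30); quadratic-in-φ variants are out of scope.
φ is stored as a fraction; the CSV reader accepts `phi_percent` and
divides by 100. Dead time t_0 is a per-run input from an unretained
marker — no estimation method is implemented. Replicate injections at
the same φ are averaged on the log k scale before the fit. The
cross-phase regression (one phase's log k_w on the other's) takes an
explicit exclusion set: the benchmark's ester-only regression
(r² = 0.898) excludes the acid pHBA, which is partially ionized at the
working pH 5 and anomalously weakly retained on both phases; exclusion
is never inferred silently.

## QSPR and comparisons

Potts–Guy coefficients are the published values for Kp in cm/s:
log10 Kp = 0.71·logP − 0.0061·MW − 6.3. The intercept is a parameter
(−2.74 gives the cm/h form). The benchmark's in-silico column is
reproduced to 2 d.p. by these coefficients for the four compounds whose
printed log P is self-consistent; the other four rows imply different
log P values were used upstream, and the compound table's `annotation`
column records the discrepancy without correcting it. Cross-method
regressions (log Kp on log k_w) record their exclusion set in the
output. Compounds with nd experimental permeability are skipped, not
imputed. The significance test is Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, two-sided.

## Simulator

Fick's second law through a single homogeneous slab (diffusivity D,
thickness ℓ, membrane/vehicle partition K), constant donor
concentration (infinite dose — the benchmark protocol used saturated
solutions) and a perfect-sink receptor boundary (5 mL stirred buffer
against µg amounts; back-diffusion ignored). The cumulative amount is
the classical series solution; terms are summed until below 1e−12 of
the running total, with at least 10 terms always summed to protect
small-t accuracy, and truncation-induced tiny negatives clamped to
zero. Derived quantities kp = D·K/ℓ and lag = ℓ²/(6D) are exposed, and
`MembraneParams.from_permeability` builds a slab realising a target
(kp, lag) with thickness a free choice (default 0.05 cm, a
full-thickness-skin scale). Measurement noise is multiplicative
Gaussian on concentration (HPLC peak-area CVs scale with signal), with
an LOD censor supplying the additive floor; one seeded generator per
simulated run, seed recorded in the ground-truth record. Donor
depletion is not modelled; transfer beyond 10% of the donor load raises
a warning that the infinite-dose assumption is strained. Default
schedule: aliquots at 0.5, 1, 2, 3, 4, 5, 6 and 24 h; default
replicates: 3.

**What the simulator does not emulate:** skin heterogeneity (stratum
corneum layering, follicular shunts), donor depletion and vehicle
evaporation, inter-cell biological variability beyond the noise model,
and ionization effects. Passing recovery tests therefore demonstrates
the pipeline's arithmetic and statistical machinery on the stated
model, not that real skin obeys a homogeneous slab.

## Numerical choices and problem sizes

OLS fits use `scipy.stats.linregress`; the Welch test uses
`scipy.stats.ttest_ind(equal_var=False)`. Tests validate these against
independent oracles: a refining brute-force grid search and a
gradient-based SSR minimizer for OLS (agreement to 1e−8), hand-coded
Welch formulas (1e−6), and a 100-node finite-difference slab solver for
the diffusion series (relative agreement better than 1e−3 at all
schedule times). Monte-Carlo checks use 1000 seeded repeats for log k_w
recovery under σ = 0.01 noise (mean error < 0.01) and 500 seeded
replicates for Kp recovery under σ = 0.05 (bias < 2%) — sizes chosen so
the whole suite runs in a few seconds while keeping Monte-Carlo
standard errors well under the asserted tolerances.

## Known limitations

- Summary-level benchmark fixtures cannot validate the calibration or
  retention stages end-to-end against real data; only simulation can.
- The maximum-flux Kp convention is noise-sensitive by construction;
  prefer the steady-state estimator when the sampling schedule supports
  it.
- The benchmark's donor concentrations are internally inconsistent with
  its printed Kp values; Cd is therefore always an explicit input and
  the package takes no side.
- No finite-dose, multi-layer, or ionization-corrected models.
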