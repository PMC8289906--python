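# Methods

## Model

The package implements a one-compartment first-order absorption model for
blood biomarker levels after concussion. An amount D0 (pg) of biomarker is
released into the brain compartment at the injury time t0 (release is
assumed complete and simultaneous; no continuing synthesis or delayed
release). The brain compartment drains into the blood with rate constant
ka (hr⁻¹); a fraction F of the release reaches the blood (bioavailability,
0.8 in every preset); the blood compartment — a single well-mixed volume
Vd (ml), approximated by total blood volume — eliminates with rate
constant ke (hr⁻¹). The mass balance

    dD_bl/dt = F·ka·D0·e^(−ka·t) − ke·D_bl,   Cp = D_bl / Vd

has the bi-exponential solution

    Cp(t) = F·D0·ka / (Vd·(ka − ke)) · (e^(−ke·t) − e^(−ka·t)),

supplemented by the relations t1/2 = 0.693/ke and
Tmax = ln(ka/ke)/(ka − ke). Assumptions worth keeping in mind: no
redistribution out of the blood (known to be dubious for S100B), no
baseline pre-injury level, and Vd treated as constant within subject.

Units are fixed package-wide — hours, pg, ml, pg/ml — with no conversion
layer.

## Numerical choices

- **ka = ke degeneracy.** The closed form is singular at ka = ke; when
  |ka − ke|/ke < 1e-8 the analytic limit F·D0·ka·t·e^(−ka·t)/Vd is used
  (and Tmax = 1/ka). The switch point leaves no visible discontinuity
  (checked to 1e-6 relative at |ka − ke|/ke = 1e-8).
- **Half-life constant.** 0.693 (the conventional printed 3-significant-
  figure value of ln 2) is the default so that derived table values are
  reproduced digit-for-digit; `exact=True` switches to `log(2)`.
- **Tmax inversion.** Tmax(ka) is strictly decreasing with value 1/ke at
  ka = ke and is symmetric under ka ↔ ke exchange (flip-flop kinetics), so
  two roots exist. The default `absorption-faster` branch (ka > ke)
  matches every published preset; the mirror branch is available by flag.
  Roots are bracketed on [ke·(1+1e-9), max(10, 100·ke)] (upper bound
  expanded ×10 as needed) and solved by Brent iteration at relative
  tolerance 1e-12. Tmax·ke = 1 returns ka = ke with a RuntimeWarning.
- **Printed-value comparisons.** "Matches the printed table" is tested as
  |computed − printed| ≤ half a unit in the last printed place, inclusive,
  because 0.693/36 = 0.01925 is an exact tie against the printed 0.0193
  and binary-float `round()` resolves such ties unpredictably.
- **D0 estimation.** The model is linear in D0 (Cp = D0·s(t)), so ordinary
  least squares has the closed form D0̂ = Σ s(tᵢ)yᵢ / Σ s(tᵢ)². Negative
  estimates are clamped to 0 by default (negative release is unphysical);
  the raw estimate is always reported alongside. Weighted least squares is
  available but off by default. All-zero shapes (every measurement at
  t = 0) raise an unidentifiability error.
- **Zero-spread degeneracies.** σ = 0 samplers return the nominal value
  exactly (not exp(log(x)), which differs in the last ulp), and band
  widths over constant draws are forced to exactly zero rather than the
  ~1e-14 artefact of `np.std`'s mean subtraction.

## Uncertainty machinery

Inputs are positive, so their uncertainty is lognormal with the
mean-preserving parameterisation p ~ lognormal(log(p_nom) − σ²/2, σ²),
giving E[p] = p_nom. Default shapes: σ = 0.3 for D0 and σ = 0.1 for Vd,
ka, ke in the joint analysis; σ = 0.2 for single-rate-constant bands.
One root seed per run is expanded into deterministic per-input substreams
(SeedSequence keyed by the input's name), so adding an input to a study
never perturbs the draws of the others, and every scenario is
bit-reproducible from (seed, configuration).

Sensitivity is the partial correlation coefficient γ of each input with
the output, adjusting linearly for the other inputs (computed by
residualisation; a rank-transform option gives the PRCC variant but is
off by default since the plain PCC is the reference analysis). One shared
1,000-row sample matrix is used across all time points of a run, which
yields smooth γ(t) curves. Significance uses
T = γ·√(N−2−p)/√(1−γ²) ~ t(N−2−p) with p = (number of varied inputs) − 1
and α = 0.05 by default (α is not prescribed by the reference analysis;
it is configurable).

The four Monte Carlo scenarios use 1,000 draws by default: joint
uncertainty (summarised by Pearson correlations of inputs with the output
at chosen times, typically 5 h and 50 h); single-rate-constant ±2δ bands
(δ = per-time output SD); draw-time jitter, uniform on
[t − hw, t + hw] — uniform being the weakest assumption for a window
stated only as "± hw" — with the study windows 6 ± 3 h and 36 ± 12 h; and
blood-volume uncertainty with sex-specific normal Vd (means 4,750 ml
women / 5,320 ml men). The Vd standard deviation is not published; the
default is 10% of the sex's mean (450 / 532 ml), an order of magnitude
consistent with published blood-volume variability, and configurable.
Nonpositive Vd draws are redrawn (truncated normal) rather than clipped,
to avoid a point mass at zero.

A note on the 36-h draw: under the printed GFAP parameters
(ka = 0.08, ke = 0.0193) the model peaks at ~23.4 h, so GFAP's level is
(slightly) *falling* at 36 h, not rising; only NF-L is still rising
there, while tau and UCH-L1 fall steeply. Similarly, the often-quoted
insensitivity of NF-L's 6-h level to draw-time error is an *absolute*
statement — its 6-h level moves by <1 pg/ml under ±3 h jitter, versus
3–5 pg/ml for the other biomarkers — whereas its *relative* spread is
actually the largest, since its level at 6 h grows nearly linearly with
time.

## Presets

Six parameterisations are registered: S100B, UCH-L1, tau, GFAP, NF-L
(literature mid-range half-life and Tmax, ke = 0.693/t1/2, ka from the
Tmax relation, all stored at printed rounding) and NF-L-Revised
(Tmax shortened to 24 h, ka = 0.2 hr⁻¹), which corrects the literature
NF-L model's under-prediction of early levels. The printed ka for UCH-L1
(0.09) and tau (0.07) are inconsistent with the Tmax relation given their
stated Tmax of 8 h (which would give ≈0.17 and ≈0.20); they are stored
verbatim, and `kinetics(recompute=True)` provides the fully self-consistent
derivation instead. Nominal inputs are D0 = 400,000 pg and Vd = 5,000 ml
throughout.

## Synthetic cohorts

The generator emulates the structure of the restricted clinical validation
cohort: four date-stamped draws per concussion, mapped to nominal hours
lt6h → 6, 24-48h → 36, asymptomatic → 168, rtp7d → 336 (plausible
midpoints — the real data are date- but not time-stamped, so any mapping
is approximate; all configurable). True draw times are jittered uniformly
around the nominal hours (half-widths 3 h and 12 h for the first two
windows, matching the stated timing uncertainty; 48 h for the loosely
scheduled later two) while only the nominal hour is "recorded", mirroring
the date-stamp approximation. Per-subject D0 is mean-preserving lognormal
(nominal 400,000 pg, σ = 0.3, matching the D0 uncertainty used in the
sensitivity analysis), with an optional two-component mixture to emulate
the bimodal release magnitudes reported in real cohorts (mixture defaults
are placeholders, not calibrated — the real cohort's mixture parameters
are unpublished). Blood volume follows the sex-specific normal model
(configurable female fraction, or a fixed Vd for controlled experiments).
Assay noise is multiplicative mean-1 lognormal with σ = 0.2 by default
(immunoassay coefficients of variation are proportional). Baseline
(pre-injury) levels default to OFF because the model ignores baseline;
when enabled, a uniform draw from the biomarker's normal plasma range is
added. A missingness rate can strip date stamps from rows, reproducing
the exclusions real data required.

What passing tests on these cohorts do **not** show about real data: the
generator draws from the same model family the estimator fits, so exact
noise-free recovery and ~11% median error under noise are statements
about estimator correctness and noise propagation, not about model
adequacy for real biology (continuing synthesis, repeat concussions,
assay detection limits and baseline drift are all unmodelled).

## Problem sizes and defaults

Monte Carlo studies default to n = 1,000 draws (matching the reference
analysis); recovery simulations use cohorts of 50–200 subjects; the
analytic AUC identity is checked on a 0–2,000 h grid at 0.1 h spacing.
The acceptance script's root-solves are deterministic and instantaneous.

## Known limitations

One compartment only; no baseline correction (listed as future work for
the underlying model); ka/ke presets carry the published rounding rather
than re-estimated uncertainty; the date-stamp-to-hours mapping makes all
cohort-level timing results qualitative; and the bimodality option is
structural, not calibrated.
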