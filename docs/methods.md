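# Methods

This note documents the models implemented in `serovolt`, the choices made
where the underlying methods left details open, and what the synthetic-data
generators do and do not emulate.

## Dual-uptake Michaelis–Menten model (`serovolt.mm`)

Evoked extracellular serotonin C(t) (nM) follows

    dC/dt = R(t)·(1 − A(t)) − α·Vmax1·C/(Km1 + C) − β·Vmax2·C/(Km2 + C)

with two saturable clearance routes: Uptake 1 (SERT: high affinity, low
capacity; default Km1 = 2 nM, Vmax1 = 12 nM s⁻¹) and Uptake 2
(DAT/NET/OCT/PMAT: low affinity, high capacity; default Km2 = 170 nM,
Vmax2 = 780 nM s⁻¹). α and β are dimensionless route weights, fixed to 1
and excluded from fitting because they are non-identifiable multipliers of
the Vmax values; they remain settable for scenario work.

**Release envelope.** The functional form of R(t) is not pinned down by the
source methods, so a smooth boxcar is used: R(t) = R_max·(1 − e^(−t/τ_on))
while the stimulus is on, then exponential relaxation with τ_off from the
value reached at stimulus end. Defaults R_max = 250 nM s⁻¹,
τ_on = τ_off = 0.3 s give peaks near 70 nM under the standard 60 Hz, 2 s
train — the tens-of-nM range typical of evoked hippocampal serotonin.

**Autoreceptor term.** A(t) is a delayed Hill function of concentration,
A(t) = A_max·C(t−δ)^h / (EC50^h + C(t−δ)^h), bounded in [0, 1) as an
occupancy must be. It defaults to off (A_max = 0): none of the quantitative
checks in this package depend on autoreceptor feedback, and enabling an
unconstrained extra mechanism would only blur parameter recovery.

**Integration.** Explicit Euler at dt = 0.01 s, resampled to the 10 Hz
acquisition grid by nearest-step lookup. A step that undershoots zero is
clamped at 0 with a logged event; a non-finite state raises an error naming
the step. Against an adaptive Runge–Kutta reference (rtol 1e-10) the
dt = 0.01 s solution is within ~0.6% sup-norm on the control
parameterisation, and the error halves with dt as expected at first order.
The constant-release steady state has a closed form (root of a quadratic
when both routes are active) used as an independent oracle.

**Fitting.** RMSE between model and trace is minimised by finite-difference
gradient descent in log-parameter space (positivity by construction) with a
backtracking Armijo line search, stopping when the relative RMSE
improvement falls below 1e-6 or after 10 000 iterations. The original
semi-automatic (manually nudged) descent is replaced by a seeded 5-start
strategy: the supplied initial guess plus log-normal jitters (SD 0.2), best
final RMSE wins. On noiseless synthetic traces the fitter recovers 10-fold
Km shifts to well under 1%; under the three canonical inhibition scenarios
(Km2 ×10; Km1 ×10; Km1 ×10 with Vmax1 ×0.5) imposed ratios are recovered
within the per-parameter 15% band by a wide margin.

## Four-compartment pharmacokinetics (`serovolt.pk`)

Peritoneum → plasma → {brain, periphery} with plasma secretion; fractions
P_B = 0.56 (plasma protein binding) and SERT_B = 0.15 (SERT binding in
brain) withhold drug from exchange; bioavailability F = 0.80 discounts the
dose; volumes 2 / 2 / 0.41 / 15 mL; 20 g mouse; escitalopram free base
324.4 g/mol (the oxalate salt is dosed, concentrations reported as free
base). The initial peritoneal concentration is
F·dose·weight / (MW·V₀) — 10 mg kg⁻¹ in a 20 g mouse gives 2.466×10⁵ nM.

**Two formulations.** The published plasma equation contains a duplicated
plasma→brain outflow where mass balance with the periphery equation
requires a plasma→periphery (k13) term. The package therefore offers:
`"as-printed"` mode with the repaired (k13) reading — the literal
duplicated form stays available behind `literal_duplicate=True` for
fidelity audits — and the default `"amount-conserving"` mode, which tracks
drug *amounts* (flows in nmol/min) and divides by compartment volume for
reporting. The printed equations exchange concentrations without volume
ratios and thus do not conserve mass between unequal compartments;
amount-conserving mode restores exact conservation (verified to ≪0.01%
over 240 min with secretion off) and is the default for that reason.

**Rate constants.** The published numeric constants live in a figure table
that is not transcribed, so the package ships no authoritative defaults:
they must be supplied in config. `synthetic_rate_constants()` provides a
documented synthetic set for tests and examples (k01 = 0.15, k10 = 0.04,
k12 = 1e-5, k21 = 0.005, k13 = 0.30, k31 = 0.01 min⁻¹), chosen once so
brain extracellular escitalopram rises quickly over the first half hour and
plateaus in the tens of nM at 10 mg kg⁻¹ — the regime where competitive
inhibition with K_i = 1.1 nM produces large apparent-Km shifts while the
1 mg kg⁻¹ dose at 5 min barely moves Km, matching the qualitative
temporo-dose picture. Because the system is linear, dose ordering and
monotonicity results do not depend on this choice.

**Solver.** Fixed-step classical Runge–Kutta (RK4) at dt = 0.01 min with an
optional dt/2 self-check; the system is small, linear and non-stiff at
tested parameters, so a fixed-step scheme with an embedded convergence
check is simpler and fully reproducible.

**Apparent Km.** Competitive inhibition inflates the SERT Michaelis
constant as Km_app = Km·(1 + [Escit.]/K_i), K_i = 1.1 nM (configurable);
the relation is exactly linear in inhibitor concentration with slope
Km/K_i. Post-drug traces are predicted by substituting Km1 → Km_app at the
brain concentration read off the trajectory; SERT binding is treated as a
constant fraction (no saturation), as printed.

## FSCV processing (`serovolt.fscv`)

- **2D filtering**: separable 3rd-order Butterworth low-pass, 37.5 kHz on
  the intra-sweep axis and 2.5 Hz on the across-sweep (10 Hz) axis,
  realised as a zero-phase magnitude response in the frequency domain on a
  symmetrically mirrored extension — this avoids edge transients on short
  recordings. DC gain is exactly 1.
- **Calibration**: background (mean of the first 10 sweeps) subtracted,
  current at the analyte's oxidation-peak sample scaled by an in vitro
  calibration factor. The factor is stored as an opaque
  "concentration units per nA" scalar with a units tag, because published
  constants mix μM nA⁻¹ and nM nA⁻¹ between waveforms.
- **Amp_max**: highest local maximum between stimulation onset and
  onset + 30 s whose prominence exceeds 3× the pre-stimulation SD, reported
  relative to the pre-stimulation mean. The 30 s window and 3×SD rule are
  package defaults (configurable) chosen to match displayed trace extents;
  they are not prescribed by the source methods. "No qualifying maximum" is
  a distinct not-found outcome, not an error.
- **Clearance**: least squares of C(t) = C_peak·e^(−k(t−t_peak)) + C_b on
  the post-peak segment; t½ = ln 2 / k holds identically. A baseline offset
  is included (the printed form has none) because traces relax to a
  non-zero ambient level; it can be pinned to 0. Non-decaying segments are
  flagged degenerate rather than raised.
- **Inhibition amplitude**: maximum dip below the pre-stimulation mean
  within 20 s of onset (configurable), reported positive, 0 when absent.

## FSCAV processing (`serovolt.fscav`)

Per 60 s file: subtract the mean of the first 10 sweeps; select the third
CV after the adsorption boundary; integrate the Faradaic peak with
Simpson's rule between bounds at the local minima flanking the window's
global maximum (5-point moving-average smoothing is used only for minima
detection; minima are strict sign changes of the first difference,
tie-broken nearest the peak; a missing flank falls back to the window edge
with a warning); subtract the trapezoid under the chord joining the
endpoint currents (capacitive baseline); convert charge to concentration by
an electrode-specific ordinary-least-squares calibration on the
10/25/50/100 nM standards (free intercept — forcing through the origin is
not assumed). Charges are in pC (nA × s × 10³); negative concentrations are
floored at 0 with a logged event. The chord subtraction removes any
straight-line background exactly when the bounds are pinned to the window
edges (`bounds="window"`); curved backgrounds leave a quadratic-order
residual, which is why the synthetic generator defaults to a linear
capacitive background. The alternative neural-network calibration used in
some prior work is out of scope; only the regression path is implemented.

## Oscillation analysis (`serovolt.oscillation`)

- **Bandpass**: 3rd-order Butterworth, 0.0008–0.005 Hz, applied
  forward-backward (zero phase), so the effective magnitude response is the
  squared 3rd-order response. At the fixed 60 s sampling the Nyquist
  frequency is 0.0083 Hz; stopband behaviour is therefore meaningful only
  below that (a 2.5-min tone is attenuated to ~8% amplitude).
- **Autocorrelation**: r_p with the full-series mean and variance; r₀ = 1
  exactly. The estimator is biased by (N−p)/N, so near-unity values at the
  oscillation period require series several periods long.
- **Sliding-window correlation**: Pearson correlation between 25-min
  windows and their lagged copies; zero-variance windows yield NaN.
- **Welch PSD**: segment length = half the series, 50% overlap, Hann
  window, constant detrend — all configurable, since the source states only
  "the Welch method". Normalised power sums to 1.
- **Weighted frequency**: WF = Σ f_i·P_norm,i, the normalised-power-weighted
  mean frequency (an unnormalised Σ f·P variant is selectable, as the
  original normalisation is ambiguous). Faster post-drug oscillations
  (positive WF shift) read as Uptake 1 inhibition, slower as Uptake 2.
  Per-animal single WF values are compared pre/post; a per-window variant
  can be built from the SWC output if distributional comparisons are
  wanted.

## Synthetic data (`serovolt.synthetic`)

The generators define the study conditions for every test:

- **Evoked traces**: the kinetic model's own forward solution (shared
  oracle) plus optional white Gaussian noise; 10 Hz sampling; 5 s
  pre-stimulation baseline; ground truth in metadata.
- **Basal series**: baseline (60 nM) + single sinusoid (period drawn
  uniformly in 6–10 min unless fixed; amplitude 5 nM) + AR(1) noise
  (stationary SD 1 nM, φ = 0.3) + an optional piecewise-linear post-drug
  ramp; one point per 60 s. A single sinusoid with AR(1) noise is the most
  parsimonious generative form consistent with a rhythm characterised only
  by period and PSD. No noise model is published for either modality, so
  amplitudes are read qualitatively from typical recordings, configurable,
  and never asserted.
- **Voltammograms**: capacitive background polynomial plus a Gaussian
  Faradaic peak whose time-integrated charge is exactly
  calibration_slope × concentration (default 0.5 pC/nM, sweep of 1000
  samples at 2.2 μs). Phenomenological only: no adsorption isotherms or
  double-layer dynamics, so passing round-trip tests demonstrates the
  correctness of the integration/calibration chain, not electrochemical
  realism.

What the generators deliberately do not emulate: electrode drift and
hysteresis, correlated multi-frequency basal dynamics, non-Gaussian
measurement noise, and stimulation artefacts. Results on real recordings
therefore depend on those factors in ways the test suite cannot certify.

## Problem sizes and numerical conventions

Simulated problem sizes are chosen to exercise each method at full fidelity
while staying desk-scale: 30 s evoked traces at dt = 0.01 s, 60–240 min
basal/PK series, 10 seeded replicates for directional statistics, 5-start
fits. All randomness flows through explicit integer seeds (one per call; no
global state); identical spec + seed is bit-identical. CSV output is UTF-8,
comma-separated, `.` decimal, with `#`-prefixed provenance comments;
`time_s` for FSCV and `time_min` for FSCAV/PK are never mixed in one file.
Statistical hypothesis tests (repeated-measures ANOVA, ANCOVA with
Tukey–Kramer, paired t-tests, Kruskal–Wallis/Dunn) are delegated to
standard libraries; the pipeline emits tidy long-format tables for them.

## Known limitations

- The release and autoreceptor functional forms are documented choices, not
  claims of equivalence to the original fitting software.
- The as-printed compartment equations are dimensionally inconsistent
  across unequal volumes; only amount-conserving mode supports conservation
  reasoning.
- Charge integration with auto-detected bounds loses the exact
  straight-line invariance (bounds move with the added line); pin
  `bounds="window"` when that invariance matters.
- The temporo-dose predictions implement pure competitive inhibition; the
  empirically observed Vmax1 reductions (transporter internalisation) are
  outside this model by design.
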