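# Methods

This note documents the models, defaults and numerical choices behind
`leafvoc`, and what the simulator-based validation does and does not show.

## 1. Cuvette mass balance and units

The chamber headspace obeys

    n dχ/dt = Q (χ_in − χ) + I A,

with `n` the headspace molar content (µmol), `Q` the molar air flow
(µmol s⁻¹), `χ` mixing ratios (nmol mol⁻¹), `I` the areal emission rate
(nmol m⁻² s⁻¹) and `A` the enclosed leaf area (m²). In these units the
static (n = 0) balance is

    I = 1e-6 · Q (χ_out − χ_in) / A,

so the default geometry (Q = 500 µmol s⁻¹, A = 6 cm²) converts one
nmol mol⁻¹ of outlet enrichment into 0.8333 nmol m⁻² s⁻¹ of emission.
`mixing_ratio_to_flux(dynamic=True)` adds the storage term
`1e-6 · (n/A) dχ/dt` (central differences on the native grid); with the
chamber content known this removes essentially all of the washout-induced
bias in the decay rate constant (the test suite demonstrates ≥80 % removal
at τ = n/Q = 5 s against k = 0.05 s⁻¹; in practice ≈99 %).

The default analysis treats the headspace as instantaneous (n = 0): a
6 cm² cuvette at 500 µmol s⁻¹ turns its air over in a few seconds, fast
relative to decay time constants of 10–100 s. The dynamic term is exposed
for slower chambers (`--chamber-molar-content`, `dynamic=True`).

Drift-tube bookkeeping: E/N = (U/L)/(p/k_B·T), reported in Townsend
(1 Td = 1e-17 V cm²). The drift length L is an instrument constant not
always reported with the operating point; the default 9.3 cm is standard
for the instrument class and is configurable. Reduced fields are
conventionally quoted to the nearest ten Td (`round_reduced_field`).

## 2. Channel registry

Sixteen default channels map exact m/z values to compounds and six
biosynthetic groups (isoprene 69.070; four LOX/GLV channels; seven reactive
carbonyls; methanol 33.034; formic/acetic acid 47.013/61.028; ethanol
47.049). The match tolerance defaults to ±0.01 Da, which keeps the
near-isobar pairs 47.013/47.049 and 59.014/59.049 separable. An observed
mass within tolerance of two entries is rejected (naming both candidates)
rather than guessed; masses outside tolerance of every entry are carried
as `unassigned` so that compound totals are conserved through grouping.

Two registry caveats are recorded rather than silently fixed: the m/z
45.034 entry keeps its printed ion formula (C₂H₂O⁺) although protonated
acetaldehyde would be C₂H₅O⁺, with the discrepancy in the entry's note
field; and formaldehyde, sometimes listed among the carbonyls, has no
stated channel and is therefore not in the default registry.

Counts→mixing-ratio calibration (primary-ion normalisation, reaction-rate
kinetics) is out of scope: the pipeline consumes channel-level mixing
ratios. A `k_rate` column is carried in the registry for users who perform
that conversion upstream.

## 3. Isoprene pool model and the simulator

The precursor pool is a single well-mixed reservoir:

    dS/dt = F·L(t) − k·S,    I(t) = k·S + E_floor,

with F the MEP supply flux under light, k the apparent IspS rate constant,
L(t) ∈ [0,1] the light schedule, and E_floor a small residual dark
emission. Within each constant-L segment the simulator evaluates the closed
form S(t) = S_eq + (S₀ − S_eq)·e^(−kt) exactly on the sampling grid, so the
generated decays are true exponentials, not integrator output. Supply is
cut instantaneously at darkening by default; an optional exponential supply
lag (`supply_lag_s`, default 0) covers non-instant cessation.

A single-pool model ties the light steady state to S* = F/k. Real leaves
show pool estimates exceeding E_ss/k (slow tail components from a second
compartment); multi-pool deconvolution is deliberately out of scope, so
simulated pools are internally consistent with the single-pool identity
rather than matching any particular field magnitude.

Simulator defaults (all configurable through `ExperimentConfig`):

- **Design**: 4 temperatures (25/30/35/40 °C) × 2 CO₂ levels (400/800
  µmol mol⁻¹) × 6 replicates = 48 leaves; PPFD 1200 µmol m⁻² s⁻¹ in the
  light phase.
- **Protocol**: 300 s light hold at steady state, then a dark tail of
  max(300 s, 6/k) at 1 Hz — long enough for the decay to exhaust
  (e⁻⁶ ≈ 0.25 % residual). A tail shorter than 5/k records a
  `dark-tail-short` warning in the ground truth.
- **Kinetics**: k log-linear in 1/T (Arrhenius form) from 0.015 s⁻¹ at
  25 °C to 0.075 s⁻¹ at 40 °C, matching the magnitude of reported apparent
  IspS rate constants at the thermal extreme; F follows the isoprene burst
  profile (below). Per-leaf lognormal variability: CV 15 % on F, 10 % on k.
- **Burst profiles**: each VOC group's steady emission is a baseline plus
  rising logistic component(s) in temperature, with an amplitude multiplier
  under elevated CO₂. Amplitudes emulate reported steady-state magnitudes
  (isoprene 1.5 → 13.3; LOX ≈ 2.4; carbonyls ≈ 450; methanol 11 → 36,
  converging across CO₂; acids ≈ 15; ethanol ≈ 50 nmol m⁻² s⁻¹ at
  40 °C / 800 ppm). Ethanol is a sum of two sigmoids — a moderate rise near
  30 °C that elevated CO₂ suppresses, and a fermentative surge at 40 °C
  that it amplifies — reproducing the biphasic pattern. All profiles are
  monotone non-decreasing in temperature.
- **Assimilation**: A_net is a treatment-level constant (declining logistic
  in temperature, ≈30 % higher at 800 ppm at 25 °C, < 2 µmol m⁻² s⁻¹ at
  40 °C ambient) plus measurement noise; it is report metadata, not a
  mechanistic photosynthesis model.
- **Noise**: multiplicative Gaussian with CV 3 % plus an additive floor of
  0.01 nmol mol⁻¹ per channel. This approximates ion-counting statistics at
  the mixing-ratio level; per-ion Poisson counting is not modelled because
  the pipeline consumes mixing ratios.
- **Blanks**: one 120 s empty-chamber trace per treatment cell at the
  ambient inlet level (0.2 nmol mol⁻¹ by default).
- **Determinism**: traces are generated from `numpy.random.SeedSequence`
  spawns, so a fixed seed is bit-reproducible and each leaf's stream is
  independent.

What the simulator does **not** emulate: instrument drift, humidity
interferences and transmission changes, stomatal dynamics during the dark
transient, multi-compartment pool tails, spectral overlap between channels,
or autocorrelated noise. Passing parameter-recovery tests therefore
validates the estimators against the stated first-order model with
well-behaved noise — not against every artefact of field data.

## 4. Decay analysis: estimators and numerical choices

- **Transition detection**: first sample with PPFD below 1 % of the
  light-phase median. Without a usable PPFD column, a change-point fallback
  on the isoprene channel takes the largest drop between adjacent 5 s means
  and refines it by least-squares matching of a plateau→exponential
  template over nearby offsets (±2 s accuracy at 3 % noise).
- **Steady state**: mean emission over the 60 s before t_off; a fitted
  trend above 5 % of the mean over the window sets `steady-state-drift`.
- **Dark baseline**: E_dark is the mean of the *final* 30 s window of the
  dark tail — the stable end state the protocol runs until. A final window
  whose |slope| exceeds 0.5 % of E_ss per second sets
  `baseline-not-reached`. The reported `baseline_start` is the earliest
  window that both satisfies the slope criterion and agrees with the floor
  within max(0.5 % of the decay amplitude, 3 SEM of the final window).
  Basing E_dark on the earliest quiet window instead would absorb residual
  decay (≈1.5 nmol m⁻² s⁻¹ at 33 s for k = 0.05) and bias the pool low by
  tens of percent.
- **Pool integration**: trapezoid of (E − E_dark) over the whole dark tail
  on the native 1 Hz grid, no resampling, no clipping of negative
  excursions (they cancel noise in expectation). Integrating the full tail
  rather than stopping at `baseline_start` costs nothing once the floor is
  subtracted and avoids an e^(−k·t_start) truncation bias. A negative total
  integral is rejected as a baseline overestimate; `baseline-not-reached`
  decays additionally carry `truncated-integral`.
- **Rate constant**: over the first 10 s after t_off, (i) `k_loglin`
  (primary): −slope of ln(E − E_dark) vs t; (ii) `k_slope`: −(least-squares
  line slope)/mean(E − E_dark) over the window — the window-mean
  normalisation is exact for first-order kinetics, where
  dE/dt = −k(E − E_dark) pointwise, leaving only ≈0.4 % curvature bias at
  k = 0.05; (iii) `k_ratio` = (E_ss − E_dark)/S_pool, the identity
  estimator. All three agree to <1 % on noise-free exponentials; their
  spread under noise is a useful diagnostic. The apparent IspS *velocity*
  (E_ss − E_dark, nmol m⁻² s⁻¹) is reported separately from the rate
  constant (s⁻¹), since "apparent IspS activity" is used for both in the
  literature.
- **Defaults**: ss_window 60 s, initial_window 10 s, baseline criterion
  (0.5 % of E_ss per s, 30 s). None of these is dictated by the measurement
  protocol itself; all are `DecayWindows` fields.
- Leaves flagged `baseline-not-reached` are excluded from treatment-level
  statistics by default (`drop_flagged`), configurably.

## 5. Treatment statistics

- **Sigmoid fits**: 4-parameter logistic
  y = y_min + (y_max − y_min)/(1 + e^(−(T − T_mid)/scale)), the minimal
  monotone saturating family consistent with the observed temperature
  responses. Deterministic multi-start `curve_fit` (midpoint quantiles ×
  two scale guesses, orientation from the T–y correlation); the best-SSE
  solution is normalised to y_max ≥ y_min. Nearly constant data return a
  flat fit flagged `degenerate`; a midpoint outside the data range ±10 °C
  is flagged. Fits need ≥4 distinct temperatures.
- **Substrate control**: OLS of emission on DMADP pool or rate constant
  with an excluded-temperature set (default {40 °C}, the decoupled
  high-velocity regime); excluded points are echoed in the result, never
  silently dropped. Requires ≥3 retained points with ≥2 distinct x values.
- **CO₂ comparisons**: independent two-tailed Student's t (pooled variance,
  df = n₁ + n₂ − 2) per temperature; Welch's variant available behind
  `equal_var=False` but never substituted silently. Stars at
  0.05/0.01/0.001. Cells with n < 2 are skipped with a note. Raw p-values
  are reported without multiple-testing correction; the ttests table
  records how many tests were run (`attrs["n_tests"]`).

## 6. Validation problem sizes

The test suite and acceptance script use the full 48-leaf design (≈700
samples × 16 channels per trace), 200 seeds for the noisy rate-constant
recovery check, 400–1000 simulated experiments for the type-I error rate,
and n = 24 points over 20–45 °C for sigmoid recovery. These sizes give
sampling error comfortably below the tolerances being checked while keeping
a full run in the tens of seconds.

## 7. Known limitations

- Single-pool decay model (no cytosolic/chloroplastic deconvolution).
- No TOF peak fitting, mass calibration or transmission correction.
- No mechanistic photosynthesis (FvCB), stomatal conductance or ROS
  chemistry; A_net and the burst profiles are descriptive response shapes.
- Blank correction subtracts a time-mean per channel per treatment cell;
  synchronous point-wise blanks are supported only for aligned series.
- The change-point fallback assumes a plateau followed by a monotone decay;
  it is not a general-purpose change-point detector.
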