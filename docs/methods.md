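# Methods

## Two-state gating model

A thermoTRP channel is treated as a closed⇌open equilibrium with
temperature-independent activation enthalpy ΔH (kcal/mol) and entropy ΔS
(cal/(mol·K)):

    ln Keq(T) = −ΔH/(R·T) + ΔS/R,   Po(T) = Keq/(1+Keq),   R = 1.987 cal/(mol·K).

For heat activation both ΔH and ΔS are large and positive; their ratio sets
the midpoint T½ = ΔH/ΔS, and their near-cancellation makes |ΔG| only a few
kcal/mol across the physiological range while Po switches steeply. Q10 is
defined as the fold change of Keq over [T, T+10 K]; we evaluate it at T½ by
default and expose the interval. The open probability is computed through
the logistic of ΔG/RT, which is overflow-free far from the midpoint.

Sign convention: Po = 1/(1 + exp(+ΔG/RT)) with ΔG = ΔH − TΔS. Statements of
this function occasionally circulate with the opposite sign in the
denominator's exponent; only the form used here is consistent with
ln Keq = −ΔH/RT + ΔS/R and with Po increasing in T for positive ΔH. All
enthalpies are stored in kcal/mol and entropies in cal/(mol·K) — the units
in which these quantities are conventionally reported — and the factor 1000
is applied exactly once, inside the closed-form gating functions.
Temperatures are Kelvin internally, Celsius at user-facing boundaries.

Channel presets pair a published ΔH with a published midpoint and derive
ΔS = 1000·ΔH/T½: RpTRPA5B (72.6 kcal/mol, 58.6 °C → ΔS ≈ 218.8), rTRPV1
(88.3, 51.6 °C → 271.9), dTRPA1D (68.7, 53.5 °C → 210.3). Published
parameter sets for these channels are not perfectly self-consistent between
figure-level and cohort-level reports (e.g. a representative-cell fit can
carry ΔH ≈ 92 kcal/mol where the cohort mean is ≈ 72.6, and a rounded ΔS of
216 with ΔH = 72 implies a midpoint of 60.2 °C rather than 58.6 °C); the
presets prioritize the (ΔH, T½) pair and treat ΔS as derived, which keeps
Po(T½) = 0.5 exact. The activation "threshold" is reported as the
temperature where Po = 0.1; note that T0.1 computed from cohort-mean
(ΔH, ΔS) (52.1 °C for RpTRPA5B) need not equal the mean of per-cell T0.1
values, and both conventions are available (`temperature_at_open_probability`
per cell, cohort means in the aggregate).

## Instrument model

**Thermal plant.** The laser-heated spot is a first-order system
dT/dt = (−(T − ambient) + gain·P)/τ with τ = 34.2 ms (the measured rise
constant of such rigs, independent of laser power), ambient 23.5 °C, and a
steady-state gain of 50 K per unit laser power with the drive clamped to
[0, 1.5] — enough headroom to reach 71.7 °C from room temperature.

**PID control.** Discrete PID with error = setpoint − temperature, output
clamped to the drive limits, and conditional-integration anti-windup (the
integral freezes while the output is saturated in the error's direction and
is clamped so the integral term alone never exceeds the output range). The
default gains kp = 0.4, ki = 20 (per-K power units; kd = 0) give an
overdamped closed loop that enters ±0.5 °C within ~60 ms at the largest
step and holds the setpoint with no measurable offset, thanks to integral
action — the steady state is independent of kp. Divergence (|T| > 500 K)
aborts with the gains named. The laser's fast on-off ripple seen in real
traces is not modelled.

**Sweep layout.** Each sweep spans the 700-ms pulse at 10 kHz with a 50-ms
laser-off lead-in, so thermometry has a clean in-sweep baseline while the
remaining 650 ms of closed loop (≈19 τ) settles long before the analysis
window. Steady-state quantities use the final 50 ms by default
(configurable); the protocol default is 12 setpoints evenly spanning
23.5–71.7 °C.

**Pipette thermometry.** Electrolyte conduction follows an Arrhenius law
with system activation energy Ea = 3.84 kcal/mol (the established value for
the CsCl/NaCl solution pair), so 1/T = 1/T0 − (R/Ea)·ln(I/I0). The
conversion is scale-invariant in current; heating 23.5 → 71.7 °C
corresponds to a current ratio of ≈ 2.49, a useful guard against cal/kcal
unit slips. Calibration replays each cell's temperature waveforms against
an open pipette and tabulates (command level, steady temperature, current
ratio); I0 is the mean over the first 40 ms of the first sweep — the
averaging convention is ours, as acquisition practice varies. The baseline
open-pipette current default (−1500 pA) only sets a realistic scale; no
result depends on it.

## Generative cell model

Whole-cell current density (pA/pF, inward negative at the −30 mV holding
potential):

    I(T) = i_leak_ref·a(T; ΔH_leak) + i_max_ref·a(T; ΔH_i)·Po(T),
    a(T; ΔH) = exp[(1000·ΔH/R)(1/T_ref − 1/T)],

i.e. a temperature-dependent leak plus a temperature-dependent maximal
channel current gated by Po. The reference-anchored Arrhenius factor
(T_ref = 23.5 °C) is algebraically identical to the raw prefactor form
prefactor·e^(−ΔH/RT) but keeps every parameter O(1). Defaults, chosen once
to produce traces of realistic magnitude for transfected HEK293T cells:
i_leak_ref = −2 pA/pF, i_max_ref = −30 pA/pF, ΔH_leak = ΔH_i = 3.84
kcal/mol (electrolyte-like), capacitance 15 pF, Gaussian measurement noise
with SD = 2% of the maximal channel current. Noise is additive and white;
single-channel gating (shot) noise and the laser ripple are not emulated,
so passing tests demonstrate correctness of the analysis chain under the
stated noise model, not robustness to every artifact of real recordings.
Between-cell variability defaults to zero (cohorts share one ground truth
and differ only in noise seed); optional Gaussian jitter on any cell
parameter is available.

Randomness uses `numpy.random.default_rng` (PCG64); sweep s of a cell
seeded with c draws from seed c·1000 + s, making recordings bit-reproducible
across platforms.

## Analysis chain

1. **Steady state**: mean current over the final 50 ms of each pulse;
   temperature from the cell's calibration table (or, for synthetic data,
   optionally the ground truth, flagged in provenance); density = I/Cm.
2. **Boltzmann fit**: least squares of the density magnitude against
   leak + gated term. The gating is parameterized as (ΔH, T½) — much better
   conditioned than (ΔH, ΔS), whose natural scales differ by ~300 K. A
   coarse grid over ΔH (20–150, step 2) × T½ (30–70 °C, step 0.5) with the
   two amplitudes solved linearly at each node (conductivity enthalpies
   held at 3.84) seeds a full 6-parameter refinement (MINPACK
   Levenberg–Marquardt via lmfit, xtol = ftol = 1e−14). ΔH_leak and ΔH_i
   are bounded to [0, 15] kcal/mol so they cannot trade off against the
   ~70 kcal/mol gating enthalpy. Requires ≥6 points spanning ≥25 °C;
   non-convergence is flagged, never silent. Amplitudes are anchored at the
   coldest pulse temperature of the data.
3. **Open probability**: Po = (|I| − leak)/g_max from the fitted leak and
   maximal-current curves. Values outside (0, 1) (noise below fitted leak,
   or above saturation) are flagged and excluded from the regression, never
   silently altered.
4. **van't Hoff**: unweighted OLS of ln(Po/(1−Po)) on 1/T over points with
   Po in [0.02, 0.98] (the logit's noise diverges outside; the window is
   our choice). Slope and intercept give the reported ΔH and ΔS; for exact
   two-state data the relation is exactly linear and the regression is
   exact. Because extreme-Po points carry both high leverage (extreme 1/T)
   and high logit variance, adding pulses near the window edges does not
   sharpen the unweighted van't Hoff estimate the way it sharpens the
   Boltzmann fit — a known property of unweighted logit regression.
5. **Derived parameters**: T0.1/T0.5/T0.9 by algebraic inversion
   T(p) = 1000·ΔH/(ΔS − R·ln(p/(1−p))), Q10 at T½, ΔG on a 20–70 °C grid.
6. **Cohort aggregation**: mean ± SEM (SD/√n; 0 with a logged caveat for
   n = 1), per-cell (ΔH, ΔS) pairs, and the enthalpy–entropy compensation
   regression of 1000·ΔH on ΔS, whose slope (in K) falls near the cohort's
   mean midpoint because estimation errors move ΔH and ΔS together along
   the T½ direction.

The van't Hoff estimates — not the Boltzmann-stage gating parameters — are
the reported ΔH/ΔS, matching the two-stage convention of the field; on
noiseless data the two stages agree to machine precision.

## Problem sizes and determinism

The standard validation condition is an 8-cell cohort, 12 pulses of 700 ms
at 10 kHz, 2% noise, seeds 1–8: small enough to run in seconds, large
enough that cohort means recover ΔH to ~0.2% and T½ to ~0.01 °C (tolerances
in the tests are far looser: ±10% and ±1 °C). `scripts/acceptance.py`
derives its cell seeds as seed…seed+7 from the single `--seed` argument.
All pipeline stages are deterministic given the configured seeds; two runs
of the same config produce identical output files.

## Limitations

- Single two-state transition only: no multi-state or allosteric gating, no
  voltage dependence (the −30 mV holding potential is metadata), no
  activation kinetics beyond the thermal plant.
- The thermal plant is a lumped first-order model; fiber-optics physics,
  convection and spatial temperature gradients across the cell are out of
  scope.
- Real-data entry is via plain-text sweep tables plus a JSON sidecar;
  vendor acquisition formats would need a thin adapter.
- The Arrhenius thermometry model is trusted over its stated range
  (~23–72 °C); conversions outside the model's validity raise rather than
  extrapolate.
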