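# trpthermo

Thermodynamic analysis of heat-gated ion channels from temperature-jump
patch-clamp recordings — with a full digital twin of the recording rig for
validation by simulation.

## The problem

Thermosensitive TRP channels ("thermoTRPs") convert heat into membrane
current. Their defining biophysics is an equilibrium between a closed and an
open conformation with unusually large, near-cancelling enthalpy and entropy
changes, which makes the open probability switch steeply over a few degrees.
Characterizing a candidate heat receptor — such as the TRPA5B channel of the
kissing bug *Rhodnius prolixus*, or the classic controls rat TRPV1 and
*Drosophila* TRPA1-D — means recovering that thermodynamic signature from
whole-cell currents evoked by fast, PID-controlled infrared temperature
jumps, where the bath temperature itself is read out from the Arrhenius
temperature dependence of an open patch pipette's current.

`trpthermo` implements both halves of that experiment in software:

- **instrument simulation** — a first-order thermal plant (rise constant
  τ ≈ 34 ms) under PID control, open-pipette current thermometry
  (Ea = 3.84 kcal/mol), and a generative model of a recorded cell
  (temperature-dependent leak, temperature-dependent maximal channel
  current, two-state gating, capacitance scaling, seeded Gaussian noise);
- **analysis** — steady-state extraction at the end of each 700-ms pulse,
  a Boltzmann fit of current density vs temperature, leak/conductivity
  correction to open probability, van't Hoff regression, and cohort
  aggregation with enthalpy–entropy compensation.

## The model

Two-state gating with temperature-independent ΔH, ΔS:

```
ln Keq(T) = −ΔH/(R·T) + ΔS/R          Po(T) = Keq/(1 + Keq)
ΔG(T)     = ΔH − T·ΔS = −RT·ln Keq    T½    = ΔH/ΔS
Q10(T)    = Keq(T+10)/Keq(T)
```

with ΔH in kcal/mol, ΔS in cal/(mol·K), R = 1.987 cal/(mol·K). The measured
current density is modelled as

```
I(T) = I_leak·a(T; ΔH_leak) + I_max·a(T; ΔH_i)·Po(T)
a(T; ΔH) = exp[(ΔH/R)(1/T_ref − 1/T)]
```

where the small Arrhenius enthalpies ΔH_leak, ΔH_i (~4 kcal/mol) describe
how leak and unitary conductance grow with temperature. Pipette-current
thermometry inverts `1/T = 1/T0 − (R/Ea)·ln(I/I0)`.

Shipped presets: RpTRPA5B (ΔH = 72.6 kcal/mol, T½ = 58.6 °C), rTRPV1
(88.3, 51.6 °C), dTRPA1D (68.7, 53.5 °C).

## Worked example

```python
import trpthermo as tp

# closed-form thermodynamics of the RpTRPA5B preset
g = tp.preset_gating("RpTRPA5B")
print(round(g.delta_s, 2))                  # 218.84  cal/(mol·K)
print(round(tp.q10_factor(g, g.t_half), 1)) # 25.1    fold per 10 °C
print(round(tp.temperature_at_open_probability(g, 0.1) - 273.15, 1))  # 52.1 °C

# full pipeline on a synthetic 8-cell cohort, 2% noise, seeds 1–8
cfg = tp.PipelineConfig(preset="RpTRPA5B", n_cells=8, seeds=tuple(range(1, 9)))
result = tp.run_pipeline(cfg, out_dir="results/demo")
m = result.cohort.mean
print(round(m["delta_h_kcal"], 1), round(m["t_half_C"], 2))  # 72.5 58.61
```

The recovered cohort means (activation enthalpy ≈ 72.5 kcal/mol, midpoint
≈ 58.6 °C) reproduce the preset ground truth through the entire simulated
measurement chain — PID pulses, pipette thermometry, Boltzmann fit, van't
Hoff regression — so the analysis is unbiased at realistic noise.

The same pipeline runs from the shell:

```sh
trpthermo run --preset RpTRPA5B --out results/demo --seed 1
trpthermo report results/demo
```

and the numbered scripts under `analysis/` tell the full story: `01` checks
the instrument model (PID settling, rise constant, thermometry round trip),
`02` recovers all three channels' published parameters from synthetic
cohorts, `03` tabulates the closed-form activation profiles.

## Layout

- `src/trpthermo/` — the library: `gating` (closed-form thermodynamics),
  `thermometry` (Arrhenius pipette calibration), `instrument` (PID rig and
  generative cell model), `fitting` (Boltzmann/van't Hoff analysis chain),
  `io`/`pipeline`/`cli` (formats, orchestration, command line).
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and limitations.
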