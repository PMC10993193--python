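"""Published activation parameters of the three heat-gated channels.

Each preset pairs an activation enthalpy (kcal/mol) with a midpoint
temperature (°C); the activation entropy follows from the midpoint
condition ΔS = 1000·ΔH/T½.  The three channels:

- ``RpTRPA5B``: the *Rhodnius prolixus* TRPA5 channel, ΔH = 72.6 kcal/mol,
  T½ = 58.6 °C (implied ΔS ≈ 218.8 cal/(mol·K), Q10 at T½ ≈ 25).
- ``rTRPV1``: rat TRPV1 control, ΔH = 88.3 kcal/mol, T½ = 51.6 °C
  (at a −30 mV holding potential).
- ``dTRPA1D``: *Drosophila* TRPA1 isoform D control, ΔH = 68.7 kcal/mol,
  T½ = 53.5 °C.

``preset_cell`` wraps a preset in the default generative cell model
(leak, conductivity temperature dependence, capacitance, noise) used by
the synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import replace

from .gating import GatingThermodynamics
from .instrument import CellParameters

__all__ = ["PRESETS", "preset_gating", "preset_cell"]

PRESETS: dict[str, GatingThermodynamics] = {
    "RpTRPA5B": GatingThermodynamics.from_midpoint(delta_h=72.6, t_half_celsius=58.6),
    "rTRPV1": GatingThermodynamics.from_midpoint(delta_h=88.3, t_half_celsius=51.6),
    "dTRPA1D": GatingThermodynamics.from_midpoint(delta_h=68.7, t_half_celsius=53.5),
}


def preset_gating(name: str) -> GatingThermodynamics:
    """Gating thermodynamics for a named channel preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def preset_cell(name: str, **overrides) -> CellParameters:
    """Default generative cell for a named channel preset.

    Keyword overrides are applied to the CellParameters fields
    (e.g. ``noise_sd_fraction=0.0`` for a noiseless cell).
    """
    cell = CellParameters(gating=preset_gating(name))
    return replace(cell, **overrides) if overrides else cell
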