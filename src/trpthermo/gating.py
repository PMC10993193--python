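"""Closed-form two-state gating thermodynamics for heat-activated channels.

A temperature-gated channel is modelled as a closed⇌open equilibrium with a
temperature-independent enthalpy change ΔH and entropy change ΔS for the
opening transition:

    ln Keq(T) = −ΔH/(R·T) + ΔS/R
    Po(T)     = Keq/(1 + Keq) = 1/(1 + exp(ΔG/(R·T))),   ΔG = ΔH − T·ΔS

For a heat-activated channel ΔH > 0 and ΔS > 0, so Po rises monotonically
with temperature and crosses 0.5 at the midpoint T½ = ΔH/ΔS (with ΔH in cal).
The thermosensitivity index Q10 is the fold-change of Keq over a 10-K
interval.

Units: ΔH in kcal/mol, ΔS in cal/(mol·K), temperatures in Kelvin.  The
kcal→cal factor is applied here and nowhere else.

Note on sign conventions: some published statements of the open-probability
denominator carry the opposite sign of ΔG.  This module uses
Po = 1/(1 + exp(+ΔG/RT)), the only form consistent with
ln Keq = −ΔH/RT + ΔS/R and with heat activation for positive ΔH, ΔS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CELSIUS_OFFSET, GAS_CONSTANT, KCAL_TO_CAL

__all__ = [
    "GatingThermodynamics",
    "equilibrium_constant",
    "open_probability",
    "temperature_at_open_probability",
    "q10_factor",
    "free_energy",
]


@dataclass(frozen=True)
class GatingThermodynamics:
    """Two-state activation parameters of a temperature-gated channel.

    Parameters
    ----------
    delta_h : float
        Activation enthalpy of the closed→open transition, kcal/mol.
    delta_s : float
        Activation entropy of the closed→open transition, cal/(mol·K).
    """

    delta_h: float
    delta_s: float

    @classmethod
    def from_midpoint(cls, delta_h: float, t_half_celsius: float) -> "GatingThermodynamics":
        """Build from enthalpy and midpoint temperature (°C).

        The entropy is fixed by the midpoint condition ΔG(T½) = 0, i.e.
        ΔS = 1000·ΔH/T½ with T½ in Kelvin.
        """
        t_half_k = t_half_celsius + CELSIUS_OFFSET
        if t_half_k <= 0:
            raise ValueError(f"midpoint temperature must be above 0 K, got {t_half_k} K")
        return cls(delta_h=delta_h, delta_s=KCAL_TO_CAL * delta_h / t_half_k)

    @property
    def t_half(self) -> float:
        """Midpoint temperature T½ = 1000·ΔH/ΔS, Kelvin."""
        return KCAL_TO_CAL * self.delta_h / self.delta_s

    @property
    def t_half_celsius(self) -> float:
        return self.t_half - CELSIUS_OFFSET

    def is_heat_activated(self) -> bool:
        return self.delta_h > 0 and self.delta_s > 0


def _check_temperature(t_kelvin) -> np.ndarray | float:
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("absolute temperature must be positive (Kelvin)")
    return t if t.ndim else float(t)


def equilibrium_constant(g: GatingThermodynamics, t_kelvin):
    """Closed⇌open equilibrium constant Keq(T) = exp(−ΔH/RT + ΔS/R).

    Strictly increasing in T for ΔH > 0.  Accepts scalars or arrays.
    """
    t = _check_temperature(t_kelvin)
    ln_keq = -KCAL_TO_CAL * g.delta_h / (GAS_CONSTANT * np.asarray(t)) + g.delta_s / GAS_CONSTANT
    return np.exp(ln_keq) if np.ndim(t) else math.exp(ln_keq)


def open_probability(g: GatingThermodynamics, t_kelvin):
    """Open probability Po(T) = Keq/(1+Keq) = 1/(1 + exp(ΔG/RT)).

    Evaluated through the logistic of ΔG/RT for numerical stability at
    temperatures far from the midpoint (where Keq under- or overflows).
    """
    t = _check_temperature(t_kelvin)
    dg_over_rt = (KCAL_TO_CAL * g.delta_h / np.asarray(t) - g.delta_s) / GAS_CONSTANT
    po = 1.0 / (1.0 + np.exp(dg_over_rt))
    return po if np.ndim(t) else float(po)


def temperature_at_open_probability(g: GatingThermodynamics, p: float) -> float:
    """Invert Po(T) = p for the two-state model.

    T = 1000·ΔH / (ΔS − R·ln(p/(1−p))).  p = 0.5 gives the midpoint,
    p = 0.1 the conventional activation 'threshold' of thermoTRP work.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"open probability must lie strictly in (0, 1), got {p}")
    denom = g.delta_s - GAS_CONSTANT * math.log(p / (1.0 - p))
    if denom <= 0:
        raise ValueError(
            f"no physical temperature reaches Po={p} for ΔS={g.delta_s} cal/(mol·K)"
        )
    return KCAL_TO_CAL * g.delta_h / denom


def q10_factor(g: GatingThermodynamics, t_kelvin: float, interval: float = 10.0) -> float:
    """Fold increase of the equilibrium constant over ``interval`` Kelvin.

    Q10 = Keq(T+10)/Keq(T) = exp((1000·ΔH/R)·10/(T·(T+10))); > 1 for a
    heat-activated channel and slowly decreasing with T.
    """
    t = _check_temperature(float(t_kelvin))
    return math.exp(
        (KCAL_TO_CAL * g.delta_h / GAS_CONSTANT) * interval / (t * (t + interval))
    )


def free_energy(g: GatingThermodynamics, t_kelvin):
    """Gibbs free energy of opening ΔG(T) = ΔH − T·ΔS/1000, kcal/mol.

    Identical to −RT·ln(Keq)/1000; zero at the midpoint temperature.
    """
    t = _check_temperature(t_kelvin)
    dg = g.delta_h - np.asarray(t) * g.delta_s / KCAL_TO_CAL
    return dg if np.ndim(t) else float(dg)
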