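"""Steady-state analysis of temperature-evoked whole-cell currents.

The chain mirrors the standard thermoTRP workflow:

1. **Steady-state extraction** — per temperature pulse, average the current
   over a window at the end of the pulse, assign the pulse temperature from
   the cell's open-pipette calibration table, and normalize by membrane
   capacitance to a current density (pA/pF).
2. **Boltzmann current–temperature fit** — least squares of the density
   magnitude against a leak term plus a conductivity-scaled two-state term:

       |I|(T) = a_leak·a(T; ΔH_leak) + a_max·a(T; ΔH_i)·Po(T; ΔH, T½)

   where a(T; ΔH) = exp((1000·ΔH/R)(1/T_ref − 1/T)) is an Arrhenius factor
   anchored at the reference (room) temperature, ΔH_leak and ΔH_i are the
   small enthalpies of leak and unitary-conductance temperature dependence,
   and Po is the two-state open probability.  A coarse grid over (ΔH, T½)
   with linear amplitude solves seeds a local refinement (lmfit/MINPACK).
3. **Leak/conductivity correction** — Po(T) = (|I|(T) − leak(T)) / g_max(T),
   the measured fraction of maximal channel current.
4. **van't Hoff regression** — ordinary least squares of
   ln Keq = ln(Po/(1−Po)) on 1/T; slope = −ΔH/R, intercept = ΔS/R.  These
   regression estimates are the reported activation enthalpy and entropy.
5. **Derived parameters** — T½, T0.1, T0.9 (temperatures at Po = 0.5, 0.1,
   0.9), Q10 at T½, and the ΔG(T) curve.
6. **Cohort aggregation** — mean ± SEM across cells, per-cell (ΔH, ΔS)
   pairs, and the enthalpy–entropy compensation regression whose slope
   approximates the mean midpoint temperature in Kelvin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .constants import CELSIUS_OFFSET, GAS_CONSTANT, KCAL_TO_CAL, kelvin_to_celsius
from .gating import (
    GatingThermodynamics,
    free_energy,
    open_probability,
    q10_factor,
    temperature_at_open_probability,
)
from .recording import Recording
from .thermometry import CalibrationTable

__all__ = [
    "SteadyStatePointSet",
    "BoltzmannFitResult",
    "VantHoffResult",
    "ActivationSummary",
    "CohortSummary",
    "extract_steady_state",
    "grid_search_boltzmann",
    "fit_boltzmann_model",
    "open_probability_series",
    "vant_hoff_regression",
    "derive_activation_parameters",
    "analyze_recording",
    "aggregate_cohort",
]

logger = logging.getLogger(__name__)

DEFAULT_STEADY_WINDOW = (0.650, 0.700)
DEFAULT_PO_WINDOW = (0.02, 0.98)
#: bounds keeping the small conductivity enthalpies from trading off
#: against the gating enthalpy (electrolyte-like values are ~4 kcal/mol)
CONDUCTIVITY_DH_BOUNDS = (0.0, 15.0)


# ---------------------------------------------------------------------------
# containers

@dataclass
class SteadyStatePointSet:
    """Per-pulse (temperature, current, current density) points for one cell.

    ``points`` columns: temperature_K, current_pA, density_pA_pF.
    """

    points: pd.DataFrame
    capacitance: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"temperature_K", "current_pA", "density_pA_pF"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"point set needs columns {sorted(required)}")
        if len(self.points) < 3:
            raise ValueError("a point set needs at least 3 pulses")
        temps = self.points["temperature_K"].to_numpy()
        if len(np.unique(np.round(temps, 9))) != len(temps):
            raise ValueError("pulse temperatures must be distinct")
        if not np.all(np.isfinite(self.points["density_pA_pF"])):
            raise ValueError("current densities must be finite")

    @property
    def temperatures(self) -> np.ndarray:
        return self.points["temperature_K"].to_numpy()

    @property
    def densities(self) -> np.ndarray:
        return self.points["density_pA_pF"].to_numpy()


@dataclass
class BoltzmannFitResult:
    """Parameters of the leak + two-state Boltzmann current-density fit."""

    i_leak_ref: float
    dh_leak: float
    i_max_ref: float
    dh_i: float
    gating: GatingThermodynamics
    t_ref: float
    residual_norm: float
    converged: bool
    stderr: dict[str, float | None] = field(default_factory=dict)
    current_sign: float = -1.0

    def leak_magnitude(self, t_kelvin) -> np.ndarray:
        t = np.asarray(t_kelvin, dtype=float)
        return abs(self.i_leak_ref) * np.exp(
            (KCAL_TO_CAL * self.dh_leak / GAS_CONSTANT) * (1 / self.t_ref - 1 / t)
        )

    def channel_max_magnitude(self, t_kelvin) -> np.ndarray:
        t = np.asarray(t_kelvin, dtype=float)
        return abs(self.i_max_ref) * np.exp(
            (KCAL_TO_CAL * self.dh_i / GAS_CONSTANT) * (1 / self.t_ref - 1 / t)
        )

    def model_magnitude(self, t_kelvin) -> np.ndarray:
        return self.leak_magnitude(t_kelvin) + self.channel_max_magnitude(
            t_kelvin
        ) * open_probability(self.gating, t_kelvin)


@dataclass
class VantHoffResult:
    """Enthalpy/entropy estimates from the ln Keq vs 1/T regression."""

    delta_h: float          # kcal/mol
    delta_s: float          # cal/(mol·K)
    r_squared: float
    n_points_used: int
    po_window: tuple[float, float]
    points: pd.DataFrame | None = None  # inv_T_per_K, ln_Keq of the points used

    @property
    def gating(self) -> GatingThermodynamics:
        return GatingThermodynamics(delta_h=self.delta_h, delta_s=self.delta_s)


@dataclass
class ActivationSummary:
    """Derived activation parameters for one cell."""

    delta_h: float          # kcal/mol
    delta_s: float          # cal/(mol·K)
    t_half_C: float
    t_010_C: float
    t_090_C: float
    q10_at_t_half: float
    delta_g: pd.DataFrame   # temperature_C, delta_g_kcal_per_mol
    r_squared: float | None = None
    cell_id: str | None = None

    def __post_init__(self) -> None:
        if not self.t_010_C < self.t_half_C < self.t_090_C:
            raise ValueError("characteristic temperatures must be ordered T0.1 < T0.5 < T0.9")


@dataclass
class CohortSummary:
    """Across-cell means ± SEM and enthalpy–entropy coupling."""

    per_cell: pd.DataFrame       # one row per cell: delta_h, delta_s, t_half_C, ...
    mean: pd.Series
    sem: pd.Series
    hs_pairs: pd.DataFrame       # delta_h_kcal, delta_s_cal per cell
    compensation_slope_K: float | None
    n_cells: int


# ---------------------------------------------------------------------------
# 1. steady-state extraction

def extract_steady_state(
    rec: Recording,
    cal: CalibrationTable | None = None,
    window: tuple[float, float] = DEFAULT_STEADY_WINDOW,
) -> SteadyStatePointSet:
    """Average each sweep over ``window`` and pair it with its pulse
    temperature.

    Temperatures come from the calibration table keyed by command level;
    with ``cal=None`` a synthetic recording's ground-truth temperatures are
    used instead (provenance flagged in the metadata).
    """
    if not rec.sweeps:
        raise ValueError("recording has no sweeps")
    records = []
    for idx, sweep in enumerate(rec.sweeps):
        current = sweep.window_mean(*window)
        if cal is not None:
            try:
                temperature = cal.temperature_for_level(sweep.command_level)
            except KeyError as exc:
                raise KeyError(
                    f"sweep {idx} (command level {sweep.command_level}): {exc}"
                ) from exc
        else:
            if rec.true_temperature is None:
                raise ValueError(
                    "no calibration table given and the recording carries no "
                    "ground-truth temperatures"
                )
            time, temps = rec.true_temperature[idx]
            mask = (time >= window[0]) & (time <= window[1])
            temperature = float(temps[mask].mean())
        records.append(
            {
                "temperature_K": temperature,
                "current_pA": current,
                "density_pA_pF": current / rec.capacitance,
            }
        )
    points = pd.DataFrame.from_records(records).sort_values("temperature_K")
    return SteadyStatePointSet(
        points=points.reset_index(drop=True),
        capacitance=rec.capacitance,
        metadata={
            "cell_id": rec.metadata.get("cell_id"),
            "window_s": window,
            "temperature_source": "calibration" if cal is not None else "ground_truth",
        },
    )


# ---------------------------------------------------------------------------
# 2. Boltzmann fit

def _design_matrix(t: np.ndarray, dh_leak: float, dh_i: float,
                   gating: GatingThermodynamics, t_ref: float) -> np.ndarray:
    """Columns: leak basis and gated-channel basis at unit amplitude."""
    inv = 1.0 / t_ref - 1.0 / t
    leak = np.exp((KCAL_TO_CAL * dh_leak / GAS_CONSTANT) * inv)
    chan = np.exp((KCAL_TO_CAL * dh_i / GAS_CONSTANT) * inv) * open_probability(gating, t)
    return np.column_stack([leak, chan])


def grid_search_boltzmann(
    t: np.ndarray,
    y: np.ndarray,
    t_ref: float,
    dh_grid: np.ndarray | None = None,
    t_half_grid_C: np.ndarray | None = None,
    dh_conductivity: float = 3.84,
) -> dict[str, float]:
    """Coarse brute-force stage: scan (ΔH, T½), solving the two amplitudes
    linearly at each node (conductivity enthalpies held at an
    electrolyte-like value).  Returns the best node's parameters.

    Also serves as an independent check on the refined optimizer.
    """
    if dh_grid is None:
        dh_grid = np.arange(20.0, 151.0, 2.0)
    if t_half_grid_C is None:
        t_half_grid_C = np.arange(30.0, 70.01, 0.5)
    best = None
    for dh in dh_grid:
        for t_half in t_half_grid_C:
            g = GatingThermodynamics.from_midpoint(dh, t_half)
            X = _design_matrix(t, dh_conductivity, dh_conductivity, g, t_ref)
            amps, *_ = np.linalg.lstsq(X, y, rcond=None)
            amps = np.clip(amps, 0.0, None)
            sse = float(np.sum((y - X @ amps) ** 2))
            if best is None or sse < best["sse"]:
                best = {
                    "sse": sse,
                    "delta_h": float(dh),
                    "t_half_C": float(t_half),
                    "a_leak": float(amps[0]),
                    "a_max": float(amps[1]),
                }
    return best


def fit_boltzmann_model(
    points: SteadyStatePointSet,
    init: dict[str, float] | None = None,
    t_ref: float | None = None,
) -> BoltzmannFitResult:
    """Fit the leak + two-state model to a cell's current-density points.

    Requires ≥6 points spanning ≥25 °C (both sub-threshold and
    near-saturating pulses are needed to separate leak from gating).
    Two-stage: coarse (ΔH, T½) grid with linear amplitudes, then local
    least-squares refinement of all six parameters.  Non-convergence is
    flagged on the result, never silent.
    """
    t = points.temperatures
    if len(t) < 6:
        raise ValueError("Boltzmann fit needs at least 6 steady-state points")
    if t.max() - t.min() < 25.0:
        raise ValueError(
            "temperature span below 25°C; extend the stimulus protocol to "
            "cover both sub-threshold and near-saturating pulses"
        )
    if t_ref is None:
        t_ref = float(t.min())

    dens = points.densities
    # fit the magnitude; remember the dominant sign to restore signed params
    sign = -1.0 if dens[np.argmax(np.abs(dens))] < 0 else 1.0
    y = sign * dens

    if init is None:
        init = grid_search_boltzmann(t, y, t_ref)

    params = lmfit.Parameters()
    params.add("a_leak", value=max(init.get("a_leak", 1.0), 1e-6), min=0.0)
    params.add("dh_leak", value=init.get("dh_leak", 3.84),
               min=CONDUCTIVITY_DH_BOUNDS[0], max=CONDUCTIVITY_DH_BOUNDS[1])
    params.add("a_max", value=max(init.get("a_max", 10.0), 1e-6), min=0.0)
    params.add("dh_i", value=init.get("dh_i", 3.84),
               min=CONDUCTIVITY_DH_BOUNDS[0], max=CONDUCTIVITY_DH_BOUNDS[1])
    params.add("delta_h", value=init.get("delta_h", 70.0), min=5.0, max=300.0)
    params.add("t_half_C", value=init.get("t_half_C", 55.0), min=25.0, max=90.0)

    def residual(p):
        g = GatingThermodynamics.from_midpoint(p["delta_h"].value, p["t_half_C"].value)
        X = _design_matrix(t, p["dh_leak"].value, p["dh_i"].value, g, t_ref)
        model = X @ np.array([p["a_leak"].value, p["a_max"].value])
        return model - y

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-14, ftol=1e-14)
    p = result.params
    gating = GatingThermodynamics.from_midpoint(p["delta_h"].value, p["t_half_C"].value)
    converged = bool(result.success and np.isfinite(result.chisqr))
    if not converged:
        logger.warning("Boltzmann fit did not converge: %s", result.message)
    return BoltzmannFitResult(
        i_leak_ref=sign * p["a_leak"].value,
        dh_leak=p["dh_leak"].value,
        i_max_ref=sign * p["a_max"].value,
        dh_i=p["dh_i"].value,
        gating=gating,
        t_ref=t_ref,
        residual_norm=float(np.sqrt(result.chisqr)),
        converged=converged,
        stderr={name: (p[name].stderr if p[name].stderr is not None else None)
                for name in p},
        current_sign=sign,
    )


# ---------------------------------------------------------------------------
# 3. leak / conductivity correction

def open_probability_series(
    points: SteadyStatePointSet, fit: BoltzmannFitResult
) -> pd.DataFrame:
    """Measured open probability per pulse after leak and conductivity
    correction: Po = (|I| − leak)/g_max.

    Returns a DataFrame with columns temperature_K, po_raw, po (clipped to
    (0, 1) exclusive) and in_range; out-of-range points are flagged, not
    dropped.
    """
    if not fit.converged:
        raise ValueError("open-probability correction requires a converged fit")
    t = points.temperatures
    g_max = fit.channel_max_magnitude(t)
    if np.any(g_max <= 0):
        raise ValueError("fitted maximal channel current is not positive")
    y = fit.current_sign * points.densities
    po_raw = (y - fit.leak_magnitude(t)) / g_max
    eps = 1e-12
    po = np.clip(po_raw, eps, 1 - eps)
    in_range = (po_raw > 0.0) & (po_raw < 1.0)
    n_out = int((~in_range).sum())
    if n_out:
        logger.info("%d of %d Po points fall outside (0, 1) and are flagged",
                    n_out, len(po_raw))
    return pd.DataFrame(
        {"temperature_K": t, "po_raw": po_raw, "po": po, "in_range": in_range}
    )


# ---------------------------------------------------------------------------
# 4. van't Hoff regression

def vant_hoff_regression(
    po_series: pd.DataFrame,
    po_window: tuple[float, float] = DEFAULT_PO_WINDOW,
) -> VantHoffResult:
    """OLS of ln Keq = ln(Po/(1−Po)) against 1/T.

    Only points with raw Po inside ``po_window`` enter the regression (the
    logit diverges at the extremes); at least 3 are required.
    ΔH = −slope·R/1000 (kcal/mol), ΔS = intercept·R (cal/(mol·K)).
    """
    lo, hi = po_window
    usable = po_series[(po_series["po_raw"] > lo) & (po_series["po_raw"] < hi)]
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} points with Po in ({lo}, {hi}); widen the "
            "temperature protocol around the activation midpoint"
        )
    inv_t = 1.0 / usable["temperature_K"].to_numpy()
    ln_keq = np.log(usable["po"] / (1.0 - usable["po"])).to_numpy()
    reg = stats.linregress(inv_t, ln_keq)
    return VantHoffResult(
        delta_h=-reg.slope * GAS_CONSTANT / KCAL_TO_CAL,
        delta_s=reg.intercept * GAS_CONSTANT,
        r_squared=float(reg.rvalue**2),
        n_points_used=int(len(usable)),
        po_window=po_window,
        points=pd.DataFrame({"inv_T_per_K": inv_t, "ln_Keq": ln_keq}),
    )


# ---------------------------------------------------------------------------
# 5. derived activation parameters

def derive_activation_parameters(
    vh: VantHoffResult,
    cell_id: str | None = None,
    delta_g_grid_C: tuple[float, float, int] = (20.0, 70.0, 51),
) -> ActivationSummary:
    """Characteristic temperatures, Q10 and ΔG(T) from a van't Hoff fit."""
    g = vh.gating
    if not g.is_heat_activated():
        raise ValueError("derived parameters assume a heat-activated fit (ΔH, ΔS > 0)")
    t_half = temperature_at_open_probability(g, 0.5)
    grid_c = np.linspace(*delta_g_grid_C)
    dg = free_energy(g, grid_c + CELSIUS_OFFSET)
    return ActivationSummary(
        delta_h=g.delta_h,
        delta_s=g.delta_s,
        t_half_C=kelvin_to_celsius(t_half),
        t_010_C=kelvin_to_celsius(temperature_at_open_probability(g, 0.1)),
        t_090_C=kelvin_to_celsius(temperature_at_open_probability(g, 0.9)),
        q10_at_t_half=q10_factor(g, t_half),
        delta_g=pd.DataFrame(
            {"temperature_C": grid_c, "delta_g_kcal_per_mol": dg}
        ),
        r_squared=vh.r_squared,
        cell_id=cell_id,
    )


def analyze_recording(
    rec: Recording,
    cal: CalibrationTable | None = None,
    window: tuple[float, float] = DEFAULT_STEADY_WINDOW,
    po_window: tuple[float, float] = DEFAULT_PO_WINDOW,
) -> tuple[BoltzmannFitResult, VantHoffResult, ActivationSummary]:
    """Run the full per-cell chain on one recording."""
    points = extract_steady_state(rec, cal, window)
    fit = fit_boltzmann_model(points)
    po = open_probability_series(points, fit)
    vh = vant_hoff_regression(po, po_window)
    summary = derive_activation_parameters(vh, cell_id=rec.metadata.get("cell_id"))
    return fit, vh, summary


# ---------------------------------------------------------------------------
# 6. cohort aggregation

def aggregate_cohort(cells: list[ActivationSummary]) -> CohortSummary:
    """Mean ± SEM of the activation parameters across cells, the per-cell
    (ΔH, ΔS) pairs, and the enthalpy–entropy compensation slope.

    The compensation regression fits 1000·ΔH (cal/mol) on ΔS (cal/(mol·K));
    its slope has units of Kelvin and is expected to sit near the cohort's
    mean midpoint temperature.  SEM is SD/√n (0 for n = 1, with a caveat
    logged).
    """
    if not cells:
        raise ValueError("cohort aggregation needs at least one cell")
    per_cell = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "delta_h_kcal": [c.delta_h for c in cells],
            "delta_s_cal": [c.delta_s for c in cells],
            "t_half_C": [c.t_half_C for c in cells],
            "t_010_C": [c.t_010_C for c in cells],
            "t_090_C": [c.t_090_C for c in cells],
            "q10_at_t_half": [c.q10_at_t_half for c in cells],
        }
    )
    numeric = per_cell.drop(columns="cell_id")
    n = len(per_cell)
    mean = numeric.mean()
    if n == 1:
        logger.warning("single-cell cohort: SEM reported as 0")
        sem = numeric.iloc[0] * 0.0
    else:
        sem = numeric.std(ddof=1) / np.sqrt(n)
    hs_pairs = per_cell[["delta_h_kcal", "delta_s_cal"]].copy()
    slope = None
    ds = hs_pairs["delta_s_cal"].to_numpy()
    if n >= 2 and np.ptp(ds) > 0:
        reg = stats.linregress(ds, KCAL_TO_CAL * hs_pairs["delta_h_kcal"].to_numpy())
        slope = float(reg.slope)
    return CohortSummary(
        per_cell=per_cell,
        mean=mean,
        sem=sem,
        hs_pairs=hs_pairs,
        compensation_slope_K=slope,
        n_cells=n,
    )
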