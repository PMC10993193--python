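"""Open-pipette current thermometry.

The ionic current through an open patch pipette rises with bath temperature
because electrolyte mobility follows an Arrhenius law.  With a system
activation energy Ea, baseline temperature T0 and baseline current I0, the
temperature that produced a current I is

    1/T = 1/T0 − (R/Ea)·ln(I/I0)

i.e. T = [1/T0 − (R/Ea)·ln(I/I0)]⁻¹.  The default Ea = 3.84 kcal/mol is the
established value for CsCl/NaCl-based recording solutions.  Heating a bath
from ~23.5 °C to ~71.7 °C corresponds to a current ratio of ≈ 2.49.

Calibration runs record one open-pipette sweep per laser command level; the
steady-state current of each sweep is converted to a temperature, producing
a per-experiment table that later assigns a temperature to every whole-cell
sweep acquired with the same command levels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import GAS_CONSTANT, KCAL_TO_CAL
from .recording import Sweep

__all__ = [
    "TemperatureCalibration",
    "CalibrationTable",
    "temperature_from_current",
    "current_ratio_for_temperature",
    "calibrate_protocol",
]

#: default baseline window: first 40 ms of the sweep (laser still off)
DEFAULT_BASELINE_WINDOW = (0.0, 0.040)
#: default steady-state window: final 50 ms of a 700-ms pulse
DEFAULT_STEADY_WINDOW = (0.650, 0.700)


@dataclass(frozen=True)
class TemperatureCalibration:
    """Arrhenius constants tying pipette current to bath temperature.

    Parameters
    ----------
    t0 : float
        Baseline (room) temperature, K.
    i0 : float
        Open-pipette current at ``t0``, pA.  Sign-carrying; conversions
        use the ratio I/I0, which must be positive.
    ea : float
        Activation energy of electrolyte conduction, kcal/mol.
    """

    t0: float
    i0: float
    ea: float = 3.84

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("baseline temperature must be positive (Kelvin)")
        if self.i0 == 0:
            raise ValueError("baseline current must be nonzero")
        if self.ea <= 0:
            raise ValueError("activation energy must be positive")


def temperature_from_current(cal: TemperatureCalibration, current):
    """Temperature (K) that produced open-pipette current ``current`` (pA).

    Accepts scalars or arrays.  Raises for current ratios outside the
    Arrhenius model's validity (ratio ≤ 0, or implied temperature ≤ 0 /
    infinite).
    """
    ratio = np.asarray(current, dtype=float) / cal.i0
    if np.any(ratio <= 0):
        raise ValueError("current must have the same sign as the baseline current")
    # Ea in cal/mol so R/Ea is dimensionless per ln-unit of current ratio
    inv_t = 1.0 / cal.t0 - (GAS_CONSTANT / (KCAL_TO_CAL * cal.ea)) * np.log(ratio)
    if np.any(inv_t <= 0):
        raise ValueError("current ratio beyond the validity of the Arrhenius model")
    t = 1.0 / inv_t
    return t if np.ndim(current) else float(t)


def current_ratio_for_temperature(cal: TemperatureCalibration, t_kelvin):
    """Open-pipette current ratio I/I0 at temperature ``t_kelvin`` (K).

    Exact algebraic inverse of :func:`temperature_from_current`:
    ln(I/I0) = (Ea/R)·(1/T0 − 1/T).
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    ratio = np.exp((KCAL_TO_CAL * cal.ea / GAS_CONSTANT) * (1.0 / cal.t0 - 1.0 / t))
    return ratio if np.ndim(t_kelvin) else float(ratio)


@dataclass
class CalibrationTable:
    """Per-experiment laser-command → temperature lookup.

    Rows are (command_level, temperature_K, current_ratio), sorted by
    command level; each cell recorded has its own table.
    """

    constants: TemperatureCalibration
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("command_level", "temperature_K", "current_ratio")

    def __post_init__(self) -> None:
        if list(self.rows.columns) != list(self.COLUMNS):
            raise ValueError(f"calibration table needs columns {self.COLUMNS}")
        self.rows = self.rows.sort_values("command_level").reset_index(drop=True)
        temps = self.rows["temperature_K"].to_numpy()
        if len(temps) > 1 and np.any(np.diff(temps) <= 0):
            raise ValueError("temperatures must increase strictly with command level")

    def temperature_for_level(self, command_level: float) -> float:
        """Steady-state temperature (K) recorded for a laser command level."""
        match = self.rows[np.isclose(self.rows["command_level"], command_level)]
        if match.empty:
            raise KeyError(f"no calibration entry for command level {command_level}")
        return float(match["temperature_K"].iloc[0])

    @property
    def temperatures(self) -> np.ndarray:
        return self.rows["temperature_K"].to_numpy()

    def to_files(self, table_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the table as TSV plus a JSON sidecar with the constants."""
        table_path = Path(table_path)
        self.rows.to_csv(table_path, sep="\t", index=False)
        sidecar = Path(sidecar_path) if sidecar_path else table_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"t0_K": self.constants.t0, "i0_pA": self.constants.i0,
                 "ea_kcal_per_mol": self.constants.ea},
                indent=2,
            )
        )

    @classmethod
    def from_files(cls, table_path: str | Path,
                   sidecar_path: str | Path | None = None) -> "CalibrationTable":
        table_path = Path(table_path)
        rows = pd.read_csv(table_path, sep="\t")
        sidecar = Path(sidecar_path) if sidecar_path else table_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        constants = TemperatureCalibration(
            t0=meta["t0_K"], i0=meta["i0_pA"], ea=meta["ea_kcal_per_mol"]
        )
        return cls(constants=constants, rows=rows)


def calibrate_protocol(
    open_pipette_sweeps: list[Sweep],
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    steady_window: tuple[float, float] = DEFAULT_STEADY_WINDOW,
    ea: float = 3.84,
    t0: float | None = None,
) -> CalibrationTable:
    """Build a calibration table from open-pipette sweeps.

    The baseline current I0 is the mean over ``baseline_window`` of the
    *first* sweep (laser off); each sweep's steady-state current is the mean
    over ``steady_window``.  ``t0`` defaults to 296.65 K (23.5 °C) when the
    sweeps carry no ``ambient_K`` metadata.

    Returns a table with one row per sweep, sorted by command level.
    """
    if not open_pipette_sweeps:
        raise ValueError("at least one open-pipette sweep is required")
    first = open_pipette_sweeps[0]
    i0 = first.window_mean(*baseline_window)
    if i0 == 0:
        raise ValueError("baseline current is zero; cannot form current ratios")
    if t0 is None:
        t0 = float(first.metadata.get("ambient_K", 296.65))
    constants = TemperatureCalibration(t0=t0, i0=i0, ea=ea)

    records = []
    for sweep in open_pipette_sweeps:
        i_ss = sweep.window_mean(*steady_window)
        records.append(
            {
                "command_level": sweep.command_level,
                "temperature_K": temperature_from_current(constants, i_ss),
                "current_ratio": i_ss / i0,
            }
        )
    rows = pd.DataFrame.from_records(records, columns=list(CalibrationTable.COLUMNS))
    return CalibrationTable(constants=constants, rows=rows)
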