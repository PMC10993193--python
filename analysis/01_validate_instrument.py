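#!/usr/bin/env python
"""Validate the simulated temperature-jump rig before any channel analysis.

Three checks on the instrument model, with tables under results/instrument/:

1. closed-loop step responses: settling time and steady-state error of the
   PID-controlled heater for setpoints across the 23.5-71.7 °C range;
2. open-loop step: the fitted rise time constant must equal the plant's
   (the measured rig rises with tau ~= 34 ms regardless of laser power);
3. pipette-current thermometry round trip: open-pipette replay of each
   pulse, converted back to temperature through the Arrhenius calibration,
   must recover the programmed steady-state temperatures.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import trpthermo as tp
from trpthermo.constants import CELSIUS_OFFSET
from trpthermo.instrument import (
    simulate_open_loop,
    simulate_pid_pulse,
    synthesize_calibration_sweeps,
)
from trpthermo.thermometry import calibrate_protocol

OUT = Path(__file__).resolve().parents[1] / "results" / "instrument"
OUT.mkdir(parents=True, exist_ok=True)

plant = tp.HeatingPlant()
gains = tp.PIDGains()
dt = 1e-4

# 1. closed-loop step responses -------------------------------------------
rows = []
for setpoint in np.linspace(23.5, 71.7, 12):
    _, temps, power = simulate_pid_pulse(plant, gains, setpoint, 0.65, dt)
    target = setpoint + CELSIUS_OFFSET
    err = np.abs(temps - target)
    settled = np.nonzero(err > 0.5)[0]
    settle_ms = (settled[-1] + 1) * dt * 1e3 if settled.size else 0.0
    rows.append(
        {
            "setpoint_C": round(setpoint, 2),
            "steady_error_C": temps[-1000:].mean() - target,
            "settle_to_0.5C_ms": settle_ms,
            "peak_power_frac": power.max() / gains.output_limits[1],
        }
    )
steps = pd.DataFrame(rows)
steps.to_csv(OUT / "pid_step_responses.tsv", sep="\t", index=False)
print("PID step responses (0.65 s of closed loop per setpoint):")
print(steps.to_string(index=False))
print(f"-> worst steady-state error {steps.steady_error_C.abs().max():.3g} °C, "
      f"slowest settling {steps['settle_to_0.5C_ms'].max():.0f} ms\n")

# 2. open-loop time constant ----------------------------------------------
time, temps = simulate_open_loop(plant, power=0.8, duration=0.5, dt=1e-5)
t_inf = plant.ambient + plant.gain * 0.8
mask = time < 5 * plant.tau
slope = np.polyfit(time[mask], np.log(t_inf - temps[mask] + 1e-300), 1)[0]
tau_fit = -1.0 / slope
pd.DataFrame([{"tau_true_s": plant.tau, "tau_fit_s": tau_fit}]).to_csv(
    OUT / "open_loop_tau.tsv", sep="\t", index=False
)
print(f"open-loop rise constant: fitted {tau_fit * 1e3:.2f} ms "
      f"vs plant {plant.tau * 1e3:.1f} ms\n")

# 3. thermometry round trip ------------------------------------------------
cell = tp.preset_cell("RpTRPA5B", noise_sd_fraction=0.0)
protocol = tp.StimulusProtocol.temperature_steps()
rec = tp.synthesize_cell_recording(cell, protocol, plant=plant, gains=gains, seed=1)
cal_constants = tp.TemperatureCalibration(t0=plant.ambient, i0=-1500.0)
table = calibrate_protocol(synthesize_calibration_sweeps(rec, cal_constants),
                           t0=plant.ambient)
round_trip = table.rows.assign(
    setpoint_C=rec.metadata["setpoints_C"],
    recovered_C=table.temperatures - CELSIUS_OFFSET,
)
round_trip.to_csv(OUT / "thermometry_round_trip.tsv", sep="\t", index=False)
worst = (round_trip.recovered_C - round_trip.setpoint_C).abs().max()
print("pipette-current thermometry round trip:")
print(round_trip[["command_level", "setpoint_C", "recovered_C", "current_ratio"]]
      .to_string(index=False))
print(f"-> worst temperature error {worst:.3f} °C; "
      f"full-range current ratio {round_trip.current_ratio.iloc[-1]:.3f} "
      "(expected ~2.49 for 23.5 -> 71.7 °C)")
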