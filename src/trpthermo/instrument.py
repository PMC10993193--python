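"""Digital twin of the infrared temperature-jump patch-clamp rig.

The heating path is modelled as a first-order thermal plant (time constant
τ ≈ 34.2 ms, matching the measured rise time of the laser-heated spot,
independent of laser power) driven by a PID controller that uses the bath
temperature as feedback:

    Err(t)    = Setpoint − T(t)
    Output(t) = Kp·Err + Ki·∫Err dτ + Kd·dErr/dt         (clamped to [0, P_max])
    dT/dt     = (−(T − ambient) + gain·Output)/τ

Anti-windup uses conditional integration: the integral term freezes while
the output is saturated in the direction the error would push it further,
and is additionally clamped so the integral contribution alone never
exceeds the output range.

On top of the thermal model sits a generative model of one recorded cell:
a temperature-dependent leak, a temperature-dependent maximal channel
current (both Arrhenius, anchored at a reference temperature), two-state
heat-activated gating, capacitance scaling to whole-cell current, and
additive Gaussian measurement noise.  Per sample,

    density(T) = i_leak_ref·a_leak(T) + i_max_ref·a_i(T)·Po(T)
    a(T)       = exp((1000·ΔH/R)·(1/T_ref − 1/T))

which is the standard leak-plus-gated-conductance current model written in
a reference-anchored form: mathematically identical to prefactor·e^(−ΔH/RT)
but with O(1) parameters.  Inward currents are negative.

Randomness: each synthetic sweep draws noise from ``numpy.random.default_rng``
(PCG64) seeded per cell; sweep s of a cell uses child seed
``cell_seed * 1000 + s``, so recordings are bit-reproducible for a given
seed on any platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .constants import CELSIUS_OFFSET, GAS_CONSTANT, KCAL_TO_CAL
from .gating import GatingThermodynamics, open_probability
from .recording import Recording, Sweep
from .thermometry import TemperatureCalibration, current_ratio_for_temperature

__all__ = [
    "PIDGains",
    "HeatingPlant",
    "StimulusProtocol",
    "CellParameters",
    "SimulationError",
    "simulate_pid_pulse",
    "simulate_open_loop",
    "simulate_open_pipette_sweep",
    "synthesize_sweep",
    "synthesize_cell_recording",
    "synthesize_calibration_sweeps",
    "synthesize_cohort",
]

logger = logging.getLogger(__name__)

#: default ambient/room temperature, K (23.5 °C)
DEFAULT_AMBIENT_K = 296.65


class SimulationError(RuntimeError):
    """Raised when a closed-loop simulation diverges."""


@dataclass(frozen=True)
class PIDGains:
    """PID gains in laser-power units per Kelvin (·s, /s for Ki, Kd).

    The defaults close the loop around the default plant with an overdamped
    response that settles well within 100 ms and leaves no steady-state
    offset (integral action).
    """

    kp: float = 0.4
    ki: float = 20.0
    kd: float = 0.0
    output_limits: tuple[float, float] = (0.0, 1.5)

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be non-negative")
        lo, hi = self.output_limits
        if not (hi > lo >= 0):
            raise ValueError("output limits must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class HeatingPlant:
    """First-order thermal model of the laser-heated spot.

    tau: thermal time constant, s; gain: steady-state K per unit laser
    power; ambient: bath temperature with the laser off, K.
    """

    tau: float = 0.0342
    gain: float = 50.0
    ambient: float = DEFAULT_AMBIENT_K

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.gain <= 0:
            raise ValueError("plant tau and gain must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Temperature-step protocol: one sweep per setpoint.

    Each sweep lasts ``pulse_duration`` seconds: the laser is off for
    ``laser_delay`` seconds (baseline for thermometry), then the PID loop
    drives the spot to the setpoint for the remainder of the pulse.
    """

    setpoints_celsius: tuple[float, ...]
    pulse_duration: float = 0.7
    laser_delay: float = 0.05
    inter_pulse: float = 2.0
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0 or self.inter_pulse < 0:
            raise ValueError("durations must be positive")
        if self.sample_rate < 1_000:
            raise ValueError("sample rate must be at least 1 kHz")
        if not 0 <= self.laser_delay < self.pulse_duration:
            raise ValueError("laser delay must lie inside the pulse")

    @classmethod
    def temperature_steps(cls, low: float = 23.5, high: float = 71.7,
                          n: int = 12, **kwargs) -> "StimulusProtocol":
        """Evenly spaced setpoints from ``low`` to ``high`` °C (default the
        23.5–71.7 °C stimulation range in 12 steps)."""
        return cls(setpoints_celsius=tuple(np.linspace(low, high, n)), **kwargs)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.pulse_duration * self.sample_rate))


@dataclass(frozen=True)
class CellParameters:
    """Generative model of one recorded cell.

    Current densities are signed (negative = inward, the convention at a
    −30 mV holding potential); ``noise_sd_fraction`` scales Gaussian
    measurement noise relative to the maximal channel current.
    """

    gating: GatingThermodynamics
    i_max_ref: float = -30.0      # pA/pF at T_ref
    dh_i: float = 3.84            # kcal/mol, conductivity temperature dependence
    i_leak_ref: float = -2.0      # pA/pF at T_ref
    dh_leak: float = 3.84         # kcal/mol
    capacitance: float = 15.0     # pF
    holding_potential: float = -30.0  # mV, metadata only
    noise_sd_fraction: float = 0.02
    t_ref: float = DEFAULT_AMBIENT_K  # K

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise fraction must be non-negative")
        if self.dh_i < 0 or self.dh_leak < 0:
            raise ValueError("conductivity enthalpies must be non-negative")

    def arrhenius_factor(self, dh: float, t_kelvin) -> np.ndarray:
        """exp((1000·dh/R)·(1/T_ref − 1/T)): 1 at T_ref, rising with T."""
        t = np.asarray(t_kelvin, dtype=float)
        return np.exp((KCAL_TO_CAL * dh / GAS_CONSTANT) * (1.0 / self.t_ref - 1.0 / t))

    def current_density(self, t_kelvin) -> np.ndarray:
        """Noise-free whole-cell current density (pA/pF) at temperature T."""
        t = np.asarray(t_kelvin, dtype=float)
        leak = self.i_leak_ref * self.arrhenius_factor(self.dh_leak, t)
        channel = (
            self.i_max_ref
            * self.arrhenius_factor(self.dh_i, t)
            * open_probability(self.gating, t)
        )
        return leak + channel


def simulate_pid_pulse(
    plant: HeatingPlant,
    gains: PIDGains,
    setpoint_celsius: float,
    duration: float,
    dt: float,
):
    """Simulate one closed-loop heating pulse.

    Returns ``(time_s, temperature_K, power)`` arrays of equal length.
    The loop starts at ambient; error is setpoint − measured so positive
    error drives heating.

    Requires ``dt ≤ tau/5`` (discretization) and ``duration ≥ 10·tau``
    (enough time to reach steady state).
    """
    if dt > plant.tau / 5:
        raise ValueError(f"dt={dt} too coarse for plant tau={plant.tau}; need dt <= tau/5")
    if duration < 10 * plant.tau:
        raise ValueError(f"duration={duration} too short; need >= 10*tau = {10 * plant.tau}")

    setpoint = setpoint_celsius + CELSIUS_OFFSET
    n = int(round(duration / dt))
    lo, hi = gains.output_limits
    temps = np.empty(n)
    powers = np.empty(n)

    t_now = plant.ambient
    integral = 0.0
    prev_err = setpoint - t_now
    int_clamp = (hi - lo) / gains.ki if gains.ki > 0 else np.inf

    for k in range(n):
        err = setpoint - t_now
        deriv = (err - prev_err) / dt
        raw = gains.kp * err + gains.ki * integral + gains.kd * deriv
        power = min(max(raw, lo), hi)
        # conditional integration: freeze the integral while saturated in
        # the direction the error would push it further
        if not ((raw >= hi and err > 0) or (raw <= lo and err < 0)):
            integral = min(max(integral + err * dt, -int_clamp), int_clamp)
        prev_err = err

        temps[k] = t_now
        powers[k] = power
        t_now += dt * (-(t_now - plant.ambient) + plant.gain * power) / plant.tau
        if not np.isfinite(t_now) or abs(t_now) > 500.0:
            raise SimulationError(
                f"PID loop diverged (|T| > 500 K) with gains "
                f"kp={gains.kp}, ki={gains.ki}, kd={gains.kd}"
            )

    time = np.arange(n) * dt
    return time, temps, powers


def simulate_open_loop(plant: HeatingPlant, power: float, duration: float, dt: float):
    """Constant-power (open-loop) step: exponential approach with the plant's
    own time constant.  Returns ``(time_s, temperature_K)``."""
    n = int(round(duration / dt))
    time = np.arange(n) * dt
    target = plant.ambient + plant.gain * power
    temps = target + (plant.ambient - target) * np.exp(-time / plant.tau)
    return time, temps


def _pulse_temperature_waveform(
    plant: HeatingPlant,
    gains: PIDGains,
    setpoint_celsius: float,
    protocol: StimulusProtocol,
):
    """Full-sweep temperature waveform: ambient during the laser delay, then
    the PID-controlled approach to the setpoint."""
    n_delay = int(round(protocol.laser_delay * protocol.sample_rate))
    heat_duration = protocol.pulse_duration - protocol.laser_delay
    _, temps, _ = simulate_pid_pulse(plant, gains, setpoint_celsius, heat_duration, protocol.dt)
    waveform = np.concatenate([np.full(n_delay, plant.ambient), temps])
    waveform = waveform[: protocol.n_samples]
    time = np.arange(waveform.size) * protocol.dt
    return time, waveform


def simulate_open_pipette_sweep(
    cal: TemperatureCalibration,
    time: np.ndarray,
    temperature: np.ndarray,
    command_level: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sweep:
    """Open-pipette current evoked by a temperature waveform.

    current(t) = I0 · (I/I0)(T(t)) via the Arrhenius calibration, with
    optional additive Gaussian noise (SD in pA).
    """
    current = cal.i0 * current_ratio_for_temperature(cal, temperature)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        current = current + rng.normal(0.0, noise_sd, size=current.shape)
    return Sweep(time=np.asarray(time), current=current, command_level=command_level,
                 metadata={"ambient_K": float(temperature[0])})


def synthesize_sweep(
    cell: CellParameters,
    time: np.ndarray,
    temperature: np.ndarray,
    command_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sweep:
    """Whole-cell current sweep evoked by a temperature waveform.

    Current in pA = density(T)·Cm plus Gaussian noise with
    SD = noise_sd_fraction·|i_max_ref·Cm|.
    """
    current = cell.current_density(temperature) * cell.capacitance
    noise_sd = cell.noise_sd_fraction * abs(cell.i_max_ref * cell.capacitance)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        current = current + rng.normal(0.0, noise_sd, size=current.shape)
    return Sweep(
        time=np.asarray(time),
        current=current,
        command_level=command_level,
        metadata={"holding_mV": cell.holding_potential},
    )


def synthesize_cell_recording(
    cell: CellParameters,
    protocol: StimulusProtocol,
    plant: HeatingPlant | None = None,
    gains: PIDGains | None = None,
    seed: int = 0,
    cell_id: str = "cell",
) -> Recording:
    """Full synthetic experiment on one cell: one PID-controlled temperature
    pulse per setpoint, each converted to a whole-cell current sweep.

    The recording stores the ground-truth temperature waveforms alongside
    the sweeps; command level s is the setpoint's index in the protocol.
    Deterministic for a given ``seed``.
    """
    plant = plant or HeatingPlant()
    gains = gains or PIDGains()
    sweeps: list[Sweep] = []
    truths: list[tuple[np.ndarray, np.ndarray]] = []
    for s, setpoint in enumerate(protocol.setpoints_celsius):
        time, temps = _pulse_temperature_waveform(plant, gains, setpoint, protocol)
        rng = np.random.default_rng(seed * 1000 + s)
        sweep = synthesize_sweep(cell, time, temps, command_level=float(s), rng=rng)
        sweep.metadata["setpoint_C"] = float(setpoint)
        sweeps.append(sweep)
        truths.append((time, temps))
    metadata = {
        "cell_id": cell_id,
        "capacitance_pF": cell.capacitance,
        "holding_mV": cell.holding_potential,
        "seed": seed,
        "setpoints_C": [float(s) for s in protocol.setpoints_celsius],
        "sample_rate_Hz": protocol.sample_rate,
        "ambient_K": plant.ambient,
    }
    return Recording(sweeps=sweeps, metadata=metadata, true_temperature=truths)


def synthesize_calibration_sweeps(
    rec: Recording,
    cal: TemperatureCalibration,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[Sweep]:
    """Open-pipette replay of a recording's laser sequence.

    Mirrors the experimental practice of re-running each cell's laser
    waveforms against an open pipette: the recording's ground-truth
    temperature waveforms are converted to open-pipette currents, one
    calibration sweep per cell sweep, sharing command levels.
    """
    if rec.true_temperature is None:
        raise ValueError("calibration replay needs ground-truth temperatures")
    rng = np.random.default_rng(seed) if seed is not None else None
    sweeps = []
    for cell_sweep, (time, temps) in zip(rec.sweeps, rec.true_temperature):
        sweeps.append(
            simulate_open_pipette_sweep(
                cal, time, temps,
                command_level=cell_sweep.command_level,
                noise_sd=noise_sd, rng=rng,
            )
        )
    return sweeps


def synthesize_cohort(
    cell: CellParameters,
    n_cells: int,
    seeds: list[int] | None = None,
    protocol: StimulusProtocol | None = None,
    plant: HeatingPlant | None = None,
    gains: PIDGains | None = None,
    noise_sd_fraction: float | None = None,
    jitter_sd: dict[str, float] | None = None,
) -> list[Recording]:
    """Generate a cohort of cells sharing one ground-truth parameter set.

    Between-cell variability defaults to zero (only measurement noise
    differs, via per-cell seeds); optional normal jitter on named
    CellParameters fields via ``jitter_sd``.
    """
    if n_cells < 1:
        raise ValueError("cohort needs at least one cell")
    seeds = list(seeds) if seeds is not None else list(range(1, n_cells + 1))
    if len(seeds) != n_cells:
        raise ValueError("one seed per cell is required")
    if len(set(seeds)) != len(seeds):
        logger.warning("duplicate seeds in cohort: recordings will share noise")
    if noise_sd_fraction is not None:
        cell = replace(cell, noise_sd_fraction=noise_sd_fraction)
    protocol = protocol or StimulusProtocol.temperature_steps()

    recordings = []
    for i, seed in enumerate(seeds):
        this_cell = cell
        if jitter_sd:
            rng = np.random.default_rng(seed + 900_000_000)
            updates = {name: getattr(cell, name) + rng.normal(0.0, sd)
                       for name, sd in jitter_sd.items()}
            this_cell = replace(cell, **updates)
        recordings.append(
            synthesize_cell_recording(
                this_cell, protocol, plant=plant, gains=gains,
                seed=seed, cell_id=f"cell{i + 1:02d}",
            )
        )
    return recordings
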