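"""Containers for patch-clamp sweeps and whole recordings.

A :class:`Sweep` is one stimulus episode: a current time series sampled at a
fixed rate, tagged with the laser command level that produced it.  A
:class:`Recording` bundles the sweeps of one cell together with metadata
(capacitance, holding potential, seed, protocol) and — for synthetic data —
the ground-truth temperature waveforms, which real recordings never have.

Sweeps serialize as two-column delimited text (time_s, current_pA) with a
JSON metadata sidecar; see :mod:`trpthermo.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Sweep", "Recording"]


@dataclass
class Sweep:
    """One current trace.

    Attributes
    ----------
    time : np.ndarray
        Sample times, s, strictly increasing, uniform.
    current : np.ndarray
        Measured current, pA (inward currents negative).
    command_level : float
        Laser command level (arbitrary units) that produced this sweep;
        the key used to look the sweep up in a calibration table.
    metadata : dict
        Free-form annotations (setpoint, seed, holding potential, ...).
    """

    time: np.ndarray
    current: np.ndarray
    command_level: float = 0.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current must have the same shape")
        if self.time.size < 2:
            raise ValueError("a sweep needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("sweep time axis must be strictly increasing")

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz, inferred from the first interval."""
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def window_mean(self, start: float, stop: float) -> float:
        """Mean current over the time window [start, stop] (s)."""
        dt = self.time[1] - self.time[0]
        # a window ending at the nominal sweep duration is valid even though
        # the last sample sits one interval before it
        if start < self.time[0] - 1e-12 or stop > self.time[-1] + dt + 1e-12:
            raise ValueError(
                f"window [{start}, {stop}] s lies outside sweep "
                f"[{self.time[0]}, {self.time[-1]}] s"
            )
        if stop <= start:
            raise ValueError("window stop must exceed window start")
        mask = (self.time >= start) & (self.time <= stop)
        if not mask.any():
            raise ValueError("window contains no samples")
        return float(self.current[mask].mean())


@dataclass
class Recording:
    """All sweeps of one cell plus metadata and (synthetic) ground truth."""

    sweeps: list[Sweep]
    metadata: dict[str, Any] = field(default_factory=dict)
    #: per-sweep (time_s, temperature_K) arrays; populated only for
    #: synthetic recordings, where the generator's temperature is known.
    true_temperature: list[tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.sweeps:
            n = self.sweeps[0].time.size
            rate = self.sweeps[0].sample_rate
            for s in self.sweeps:
                if s.time.size != n or abs(s.sample_rate - rate) > 1e-6 * rate:
                    raise ValueError("all sweeps must share sample rate and length")
        if self.true_temperature is not None and len(self.true_temperature) != len(self.sweeps):
            raise ValueError("one ground-truth temperature trace per sweep required")

    @property
    def capacitance(self) -> float:
        return float(self.metadata["capacitance_pF"])

    @property
    def is_synthetic(self) -> bool:
        return self.true_temperature is not None
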