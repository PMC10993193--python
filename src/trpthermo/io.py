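"""Text-first file formats for sweeps, recordings and calibration tables.

Sweeps are two-column tab-delimited tables with the header
``time_s<TAB>current_pA`` (ground-truth temperature traces use
``time_s<TAB>temperature_K``).  A recording is a directory of sweep files
plus a ``metadata.json`` sidecar listing the files, command levels,
capacitance, holding potential, seed and protocol, so every recording is
self-describing and reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording, Sweep

__all__ = [
    "read_sweep_table",
    "write_sweep_table",
    "write_recording",
    "read_recording",
]

SWEEP_COLUMNS = ("time_s", "current_pA")
TRUTH_COLUMNS = ("time_s", "temperature_K")


def write_sweep_table(sweep: Sweep, path: str | Path) -> None:
    """Write one sweep as a two-column delimited text table."""
    df = pd.DataFrame({"time_s": sweep.time, "current_pA": sweep.current})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sweep_table(path: str | Path, command_level: float = 0.0) -> Sweep:
    """Read a sweep from a two-column table with header time_s, current_pA.

    The header names carry the units; a malformed header or a non-monotone
    time axis is a format error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = tuple(df.columns)
    if cols != SWEEP_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {SWEEP_COLUMNS}, found {cols} "
            "(units are taken from the header names)"
        )
    time = df["time_s"].to_numpy(dtype=float)
    current = df["current_pA"].to_numpy(dtype=float)
    if np.any(~np.isfinite(time)) or np.any(~np.isfinite(current)):
        raise ValueError(f"{path}: non-numeric values in sweep table")
    if np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: time axis must be strictly increasing")
    return Sweep(time=time, current=current, command_level=command_level)


def write_recording(rec: Recording, directory: str | Path) -> Path:
    """Write a recording as per-sweep tables plus a JSON metadata sidecar.

    Synthetic recordings also get one ground-truth temperature table per
    sweep.  Returns the directory path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sweep_entries = []
    for i, sweep in enumerate(rec.sweeps):
        fname = f"sweep{i:02d}.tsv"
        write_sweep_table(sweep, directory / fname)
        entry = {"file": fname, "command_level": sweep.command_level,
                 "metadata": sweep.metadata}
        if rec.true_temperature is not None:
            tname = f"truth{i:02d}.tsv"
            time, temps = rec.true_temperature[i]
            pd.DataFrame({"time_s": time, "temperature_K": temps}).to_csv(
                directory / tname, sep="\t", index=False, float_format="%.8g"
            )
            entry["truth_file"] = tname
        sweep_entries.append(entry)
    sidecar = {"metadata": rec.metadata, "sweeps": sweep_entries}
    (directory / "metadata.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_recording(directory: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "metadata.json").read_text())
    sweeps, truths = [], []
    has_truth = all("truth_file" in e for e in sidecar["sweeps"])
    for entry in sidecar["sweeps"]:
        sweep = read_sweep_table(directory / entry["file"],
                                 command_level=entry["command_level"])
        sweep.metadata.update(entry.get("metadata", {}))
        sweeps.append(sweep)
        if has_truth:
            df = pd.read_csv(directory / entry["truth_file"], sep="\t")
            truths.append((df["time_s"].to_numpy(), df["temperature_K"].to_numpy()))
    return Recording(
        sweeps=sweeps,
        metadata=sidecar["metadata"],
        true_temperature=truths if has_truth else None,
    )
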