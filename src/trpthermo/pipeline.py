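"""End-to-end orchestration: simulate → calibrate → extract → fit → report.

``run_pipeline`` executes the whole analysis on a synthetic cohort:

1. generate one recording per cell from a channel preset (PID-controlled
   temperature pulses, generative cell model, seeded noise);
2. replay each cell's laser sequence against an open pipette and build its
   thermometry calibration table;
3. extract steady-state points, fit the Boltzmann current-density model,
   correct to open probability, run the van't Hoff regression and derive
   the activation parameters per cell;
4. aggregate across the cohort.

Every run writes its configuration, seeds and package version beside the
outputs so the result directory reproduces itself exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .fitting import (
    ActivationSummary,
    CohortSummary,
    aggregate_cohort,
    analyze_recording,
)
from .instrument import (
    HeatingPlant,
    PIDGains,
    StimulusProtocol,
    synthesize_calibration_sweeps,
    synthesize_cohort,
)
from .io import write_recording
from .presets import PRESETS, preset_cell
from .thermometry import TemperatureCalibration, calibrate_protocol

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


def _from_dict(cls, data: dict[str, Any]):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable description of one cohort analysis run."""

    preset: str = "RpTRPA5B"
    n_cells: int = 8
    seeds: tuple[int, ...] | None = None        # defaults to 1..n_cells
    noise_sd_fraction: float = 0.02
    cell_overrides: dict[str, float] = field(default_factory=dict)
    protocol: dict[str, Any] = field(default_factory=dict)   # temperature_steps kwargs
    plant: dict[str, float] = field(default_factory=dict)    # HeatingPlant kwargs
    pid: dict[str, Any] = field(default_factory=dict)        # PIDGains kwargs
    calibration_i0: float = -1500.0   # open-pipette baseline current, pA
    calibration_ea: float = 3.84      # kcal/mol
    steady_window: tuple[float, float] = (0.650, 0.700)
    po_window: tuple[float, float] = (0.02, 0.98)
    write_sweeps: bool = False        # persist raw sweep tables (bulky)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = dict(data)
        for key in ("seeds", "steady_window", "po_window"):
            if key in cfg and cfg[key] is not None:
                cfg[key] = tuple(cfg[key])
        return _from_dict(cls, cfg)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def resolved_seeds(self) -> list[int]:
        return list(self.seeds) if self.seeds is not None else list(range(1, self.n_cells + 1))


@dataclass
class PipelineResult:
    cohort: CohortSummary
    cells: list[ActivationSummary]
    config: PipelineConfig


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full cohort analysis described by ``config``.

    Deterministic given the config's seeds.  When ``out_dir`` is set,
    writes per-cell JSON summaries, the cohort table, van't Hoff point
    tables and the run configuration there.  Any stage failure aborts with
    the stage and cell named.
    """
    cell = preset_cell(config.preset, **config.cell_overrides)
    protocol = StimulusProtocol.temperature_steps(**config.protocol)
    plant = _from_dict(HeatingPlant, config.plant)
    gains = _from_dict(PIDGains, config.pid)
    seeds = config.resolved_seeds()

    try:
        recordings = synthesize_cohort(
            cell, config.n_cells, seeds=seeds, protocol=protocol,
            plant=plant, gains=gains, noise_sd_fraction=config.noise_sd_fraction,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    cal_constants = TemperatureCalibration(
        t0=plant.ambient, i0=config.calibration_i0, ea=config.calibration_ea
    )

    cells: list[ActivationSummary] = []
    fits, vhs, cals = [], [], []
    for rec in recordings:
        cid = rec.metadata["cell_id"]
        try:
            open_pipette = synthesize_calibration_sweeps(rec, cal_constants)
            cal = calibrate_protocol(open_pipette, ea=config.calibration_ea,
                                     t0=plant.ambient)
        except Exception as exc:
            raise RuntimeError(f"stage 'calibrate' failed for {cid}: {exc}") from exc
        try:
            fit, vh, summary = analyze_recording(
                rec, cal, window=config.steady_window, po_window=config.po_window
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'fit' failed for {cid}: {exc}") from exc
        cells.append(summary)
        fits.append(fit)
        vhs.append(vh)
        cals.append(cal)

    try:
        cohort = aggregate_cohort(cells)
    except Exception as exc:
        raise RuntimeError(f"stage 'aggregate' failed: {exc}") from exc

    result = PipelineResult(cohort=cohort, cells=cells, config=config)
    if out_dir is not None:
        _write_artifacts(result, recordings, fits, vhs, cals, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, recordings, fits, vhs, cals,
                     out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config
    (out_dir / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "seeds": config.resolved_seeds(),
                    "trpthermo_version": __version__}, indent=2)
    )
    result.cohort.per_cell.to_csv(out_dir / "per_cell.tsv", sep="\t", index=False)
    summary = pd.DataFrame({"mean": result.cohort.mean, "sem": result.cohort.sem})
    summary.to_csv(out_dir / "cohort_summary.tsv", sep="\t")
    extra = {
        "n_cells": result.cohort.n_cells,
        "compensation_slope_K": result.cohort.compensation_slope_K,
    }
    (out_dir / "cohort_summary.json").write_text(json.dumps(
        {**extra, "mean": result.cohort.mean.to_dict(),
         "sem": result.cohort.sem.to_dict()}, indent=2))

    for rec, cell, fit, vh, cal in zip(recordings, result.cells, fits, vhs, cals):
        cid = rec.metadata["cell_id"]
        cell_dir = out_dir / cid
        cell_dir.mkdir(exist_ok=True)
        (cell_dir / "summary.json").write_text(json.dumps({
            "cell_id": cid,
            "delta_h_kcal": cell.delta_h,
            "delta_s_cal": cell.delta_s,
            "t_half_C": cell.t_half_C,
            "t_010_C": cell.t_010_C,
            "t_090_C": cell.t_090_C,
            "q10_at_t_half": cell.q10_at_t_half,
            "r_squared": cell.r_squared,
            "boltzmann": {
                "i_leak_ref": fit.i_leak_ref, "dh_leak": fit.dh_leak,
                "i_max_ref": fit.i_max_ref, "dh_i": fit.dh_i,
                "delta_h": fit.gating.delta_h,
                "t_half_C": fit.gating.t_half_celsius,
                "t_ref_K": fit.t_ref,
                "residual_norm": fit.residual_norm,
                "converged": fit.converged,
            },
            "seed": rec.metadata.get("seed"),
        }, indent=2))
        if vh.points is not None:
            vh.points.to_csv(cell_dir / "vant_hoff_points.tsv", sep="\t", index=False)
        cal.to_files(cell_dir / "calibration.tsv")
        if config.write_sweeps:
            write_recording(rec, cell_dir / "recording")
    logger.info("pipeline artifacts written to %s", out_dir)
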