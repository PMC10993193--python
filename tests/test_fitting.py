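"""Steady-state extraction, Boltzmann fit, van't Hoff regression, cohort
aggregation."""

import numpy as np
import pandas as pd
import pytest

import trpthermo as tp
from trpthermo.constants import CELSIUS_OFFSET
from trpthermo.fitting import (
    DEFAULT_PO_WINDOW,
    SteadyStatePointSet,
    grid_search_boltzmann,
)

TWELVE_STEPS_K = np.linspace(23.5, 71.7, 12) + CELSIUS_OFFSET


def points_from_cell(cell, temps_K=TWELVE_STEPS_K, noise_sd_density=0.0, rng=None):
    """Steady-state points computed directly from the generative model."""
    dens = cell.current_density(temps_K)
    if noise_sd_density > 0:
        dens = dens + rng.normal(0.0, noise_sd_density, size=dens.shape)
    return SteadyStatePointSet(
        points=pd.DataFrame(
            {
                "temperature_K": temps_K,
                "current_pA": dens * cell.capacitance,
                "density_pA_pF": dens,
            }
        ),
        capacitance=cell.capacitance,
    )


@pytest.fixture(scope="module")
def noiseless_cell(rptrpa5b=None):
    return tp.preset_cell("RpTRPA5B", noise_sd_fraction=0.0)


@pytest.fixture(scope="module")
def noiseless_fit(noiseless_cell):
    points = points_from_cell(noiseless_cell)
    return points, tp.fit_boltzmann_model(points)


class TestExtractSteadyState:
    def test_constant_sweep(self, rptrpa5b):
        time = np.arange(7000) * 1e-4
        sweeps = [
            tp.Sweep(time=time, current=np.full(7000, -120.0 - 10 * k),
                     command_level=float(k))
            for k in range(3)
        ]
        truth = [(time, np.full(7000, 300.0 + 10 * k)) for k in range(3)]
        rec = tp.Recording(sweeps=sweeps, metadata={"capacitance_pF": 12.0},
                           true_temperature=truth)
        pts = tp.extract_steady_state(rec)
        assert np.allclose(pts.points["current_pA"], [-120.0, -130.0, -140.0])
        assert np.allclose(pts.densities, np.array([-120.0, -130.0, -140.0]) / 12.0)

    def test_recovers_generator_ground_truth(self, noiseless_recording):
        cell, rec = noiseless_recording
        cal_constants = tp.TemperatureCalibration(t0=296.65, i0=-1500.0)
        from trpthermo.instrument import synthesize_calibration_sweeps
        from trpthermo.thermometry import calibrate_protocol

        cal = calibrate_protocol(synthesize_calibration_sweeps(rec, cal_constants),
                                 t0=296.65)
        pts = tp.extract_steady_state(rec, cal)
        setpoints_K = np.array(rec.metadata["setpoints_C"]) + CELSIUS_OFFSET
        assert np.allclose(np.sort(pts.temperatures), setpoints_K, atol=0.3)
        expected = cell.current_density(pts.temperatures) * cell.capacitance
        assert np.allclose(pts.points["current_pA"], expected, rtol=5e-3)

    def test_window_outside_sweep_rejected(self, noiseless_recording):
        _, rec = noiseless_recording
        with pytest.raises(ValueError):
            tp.extract_steady_state(rec, window=(0.6, 1.4))

    def test_missing_calibration_entry_names_sweep(self, noiseless_recording):
        _, rec = noiseless_recording
        rows = pd.DataFrame(
            {"command_level": [99.0], "temperature_K": [300.0], "current_ratio": [1.1]}
        )
        cal = tp.CalibrationTable(
            constants=tp.TemperatureCalibration(t0=296.65, i0=-1500.0), rows=rows
        )
        with pytest.raises(KeyError, match="command level"):
            tp.extract_steady_state(rec, cal)


class TestBoltzmannFit:
    def test_noiseless_recovery_below_0p1_percent(self, noiseless_cell, noiseless_fit):
        _, fit = noiseless_fit
        truth = noiseless_cell
        assert fit.converged
        assert fit.gating.delta_h == pytest.approx(truth.gating.delta_h, rel=1e-3)
        assert fit.gating.delta_s == pytest.approx(truth.gating.delta_s, rel=1e-3)
        # amplitudes are anchored at the coldest pulse; map truth to that anchor
        scale_leak = np.exp((1000 * truth.dh_leak / 1.987)
                            * (1 / truth.t_ref - 1 / fit.t_ref))
        scale_i = np.exp((1000 * truth.dh_i / 1.987)
                         * (1 / truth.t_ref - 1 / fit.t_ref))
        assert fit.i_leak_ref == pytest.approx(truth.i_leak_ref * scale_leak, rel=1e-3)
        assert fit.i_max_ref == pytest.approx(truth.i_max_ref * scale_i, rel=1e-3)
        assert fit.dh_leak == pytest.approx(truth.dh_leak, rel=1e-3)
        assert fit.dh_i == pytest.approx(truth.dh_i, rel=1e-3)

    def test_leak_only_cell(self, rptrpa5b):
        cell = tp.CellParameters(gating=rptrpa5b, i_max_ref=0.0, noise_sd_fraction=0.0)
        fit = tp.fit_boltzmann_model(points_from_cell(cell))
        assert abs(fit.i_max_ref) < 0.05 * abs(cell.i_leak_ref)
        assert fit.i_leak_ref == pytest.approx(cell.i_leak_ref, rel=0.01)

    def test_grid_oracle_agrees_with_refined_fit(self, noiseless_fit):
        points, fit = noiseless_fit
        best = grid_search_boltzmann(points.temperatures,
                                     -points.densities, fit.t_ref)
        assert abs(best["delta_h"] - fit.gating.delta_h) <= 2.0
        assert abs(best["t_half_C"] - fit.gating.t_half_celsius) <= 0.5

    def test_too_few_points_rejected(self, noiseless_cell):
        with pytest.raises(ValueError):
            tp.fit_boltzmann_model(
                points_from_cell(noiseless_cell, temps_K=TWELVE_STEPS_K[:5])
            )

    def test_narrow_span_rejected(self, noiseless_cell):
        temps = np.linspace(50.0, 70.0, 8) + CELSIUS_OFFSET
        with pytest.raises(ValueError, match="span"):
            tp.fit_boltzmann_model(points_from_cell(noiseless_cell, temps_K=temps))


class TestOpenProbabilitySeries:
    def test_half_at_midpoint(self, noiseless_cell, noiseless_fit):
        points, fit = noiseless_fit
        po = tp.open_probability_series(points, fit)
        t_half = noiseless_cell.gating.t_half
        interp = np.interp(t_half, po["temperature_K"], po["po"])
        # the two pulses bracketing T0.5 pin the interpolated Po near 0.5
        assert interp == pytest.approx(0.5, abs=0.02)
        exact = points_from_cell(noiseless_cell, temps_K=np.array([t_half, 300.0, 320.0]))
        po_exact = tp.open_probability_series(exact, fit)
        assert po_exact["po"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_near_saturation_value(self, noiseless_cell, noiseless_fit):
        # at 68.6 °C, Keq ≈ 25.1 so the corrected Po should be Keq/(1+Keq)
        _, fit = noiseless_fit
        t = np.array([341.75, 300.0, 320.0])
        pts = points_from_cell(noiseless_cell, temps_K=t)
        po = tp.open_probability_series(pts, fit)
        assert po["po"].iloc[0] == pytest.approx(25.0957 / 26.0957, abs=1e-4)

    def test_point_below_leak_flagged_not_dropped(self, noiseless_cell, noiseless_fit):
        points, fit = noiseless_fit
        modified = points.points.copy()
        # force the coldest pulse below the fitted leak
        modified.loc[0, "density_pA_pF"] = modified.loc[0, "density_pA_pF"] * 0.5
        pts = SteadyStatePointSet(points=modified, capacitance=points.capacitance)
        po = tp.open_probability_series(pts, fit)
        assert len(po) == len(points.points)
        assert not po["in_range"].iloc[0]
        vh = tp.vant_hoff_regression(po)
        assert vh.n_points_used < len(po)

    def test_unconverged_fit_rejected(self, noiseless_fit):
        import dataclasses

        points, fit = noiseless_fit
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError):
            tp.open_probability_series(points, bad)


class TestVantHoff:
    def test_exact_on_analytic_po(self, rptrpa5b):
        temps = np.linspace(320.0, 345.0, 9)
        po_raw = tp.open_probability(rptrpa5b, temps)
        series = pd.DataFrame(
            {"temperature_K": temps, "po_raw": po_raw, "po": po_raw,
             "in_range": np.ones_like(temps, bool)}
        )
        vh = tp.vant_hoff_regression(series)
        # ln Keq vs 1/T is exactly linear for the two-state model
        assert vh.delta_h == pytest.approx(rptrpa5b.delta_h, rel=1e-12)
        assert vh.delta_s == pytest.approx(rptrpa5b.delta_s, rel=1e-12)
        assert vh.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_cell_within_ten_percent(self, rptrpa5b):
        # 2% trace noise averaged over the 500-sample steady window leaves
        # per-point density noise of 2%·|i_max|/√500
        cell = tp.preset_cell("RpTRPA5B")
        rng = np.random.default_rng(1)
        noise_sd = cell.noise_sd_fraction * abs(cell.i_max_ref) / np.sqrt(500)
        pts = points_from_cell(cell, noise_sd_density=noise_sd, rng=rng)
        fit = tp.fit_boltzmann_model(pts)
        vh = tp.vant_hoff_regression(tp.open_probability_series(pts, fit))
        assert vh.delta_h == pytest.approx(72.6, rel=0.10)

    def test_all_points_outside_window_rejected(self):
        temps = np.array([300.0, 305.0, 310.0])
        series = pd.DataFrame(
            {"temperature_K": temps, "po_raw": [1e-4, 2e-4, 5e-4],
             "po": [1e-4, 2e-4, 5e-4], "in_range": [True] * 3}
        )
        with pytest.raises(ValueError, match="widen"):
            tp.vant_hoff_regression(series, DEFAULT_PO_WINDOW)


class TestDerivedParameters:
    @pytest.mark.parametrize(
        "delta_h, delta_s, t_half_C, q10",
        [
            (72.6, 218.84, 58.6, 25.1),    # RpTRPA5B: published midpoint and Q10
            (88.3, 271.90, 51.6, None),    # rTRPV1 control
            (68.7, 210.34, 53.5, None),    # dTRPA1-D control
        ],
    )
    def test_published_parameter_pairs(self, delta_h, delta_s, t_half_C, q10):
        vh = tp.VantHoffResult(delta_h=delta_h, delta_s=delta_s, r_squared=1.0,
                               n_points_used=6, po_window=DEFAULT_PO_WINDOW)
        summary = tp.derive_activation_parameters(vh)
        assert summary.t_half_C == pytest.approx(t_half_C, abs=0.1)
        assert summary.t_010_C < summary.t_half_C < summary.t_090_C
        if q10 is not None:
            assert summary.q10_at_t_half == pytest.approx(q10, rel=0.01)

    def test_activation_threshold_ordering(self, rptrpa5b):
        vh = tp.VantHoffResult(delta_h=rptrpa5b.delta_h, delta_s=rptrpa5b.delta_s,
                               r_squared=1.0, n_points_used=6,
                               po_window=DEFAULT_PO_WINDOW)
        s = tp.derive_activation_parameters(vh)
        # Po(T) evaluated back at the derived temperatures
        for target, t_c in [(0.1, s.t_010_C), (0.5, s.t_half_C), (0.9, s.t_090_C)]:
            assert tp.open_probability(rptrpa5b, t_c + CELSIUS_OFFSET) == pytest.approx(
                target, rel=1e-9
            )

    def test_cold_activated_fit_rejected(self):
        vh = tp.VantHoffResult(delta_h=-40.0, delta_s=-120.0, r_squared=1.0,
                               n_points_used=5, po_window=DEFAULT_PO_WINDOW)
        with pytest.raises(ValueError):
            tp.derive_activation_parameters(vh)


class TestEstimatorConsistency:
    def test_error_shrinks_with_noise_and_grows_sparser(self, rptrpa5b):
        """Recovery error of the fitted activation enthalpy decreases as the
        noise goes to zero and as the protocol gains pulses (3 noise levels
        × 2 grid densities, averaged over seeds)."""
        cell = tp.preset_cell("RpTRPA5B")
        base_sd = cell.noise_sd_fraction * abs(cell.i_max_ref) / np.sqrt(500)
        errors = {}
        for n_points in (12, 24):
            temps = np.linspace(23.5, 71.7, n_points) + CELSIUS_OFFSET
            for mult in (4.0, 1.0, 0.0):
                errs = []
                for seed in range(16):
                    rng = np.random.default_rng(100 + seed)
                    pts = points_from_cell(
                        cell, temps_K=temps,
                        noise_sd_density=mult * base_sd, rng=rng,
                    )
                    fit = tp.fit_boltzmann_model(pts)
                    errs.append(abs(fit.gating.delta_h - 72.6) / 72.6)
                errors[(n_points, mult)] = np.mean(errs)
        for n_points in (12, 24):
            assert errors[(n_points, 0.0)] < errors[(n_points, 1.0)]
            assert errors[(n_points, 1.0)] < errors[(n_points, 4.0)]
        for mult in (4.0, 1.0):
            assert errors[(24, mult)] < errors[(12, mult)]


class TestLeakCorrection:
    def test_idempotence(self, noiseless_cell, noiseless_fit):
        """Refitting the leak-corrected channel component returns ~zero leak."""
        points, fit = noiseless_fit
        t = points.temperatures
        corrected = -(fit.channel_max_magnitude(t)
                      * tp.open_probability(fit.gating, t))
        pts = SteadyStatePointSet(
            points=pd.DataFrame(
                {"temperature_K": t, "current_pA": corrected * points.capacitance,
                 "density_pA_pF": corrected}
            ),
            capacitance=points.capacitance,
        )
        refit = tp.fit_boltzmann_model(pts)
        assert abs(refit.i_leak_ref) < 1e-3 * abs(refit.i_max_ref)
        assert refit.gating.delta_h == pytest.approx(fit.gating.delta_h, rel=1e-3)


class TestCohortAggregation:
    def test_identical_cells_have_zero_sem(self, rptrpa5b):
        vh = tp.VantHoffResult(delta_h=rptrpa5b.delta_h, delta_s=rptrpa5b.delta_s,
                               r_squared=1.0, n_points_used=6,
                               po_window=DEFAULT_PO_WINDOW)
        cells = [tp.derive_activation_parameters(vh, cell_id=f"c{i}") for i in range(4)]
        cohort = tp.aggregate_cohort(cells)
        assert (cohort.sem == 0).all()
        assert cohort.mean["t_half_C"] == pytest.approx(58.6, abs=0.01)

    def test_preset_cohort_midpoint_and_compensation(self, rptrpa5b_cohort):
        cohort = rptrpa5b_cohort.cohort
        assert cohort.mean["t_half_C"] == pytest.approx(58.6, abs=1.0)
        # enthalpy–entropy compensation: slope ≈ mean midpoint in Kelvin
        assert cohort.compensation_slope_K == pytest.approx(332.0, abs=5.0)

    def test_single_cell_cohort_logs_caveat(self, rptrpa5b, caplog):
        vh = tp.VantHoffResult(delta_h=rptrpa5b.delta_h, delta_s=rptrpa5b.delta_s,
                               r_squared=1.0, n_points_used=6,
                               po_window=DEFAULT_PO_WINDOW)
        with caplog.at_level("WARNING", logger="trpthermo.fitting"):
            cohort = tp.aggregate_cohort([tp.derive_activation_parameters(vh)])
        assert cohort.n_cells == 1
        assert (cohort.sem == 0).all()
        assert any("SEM" in r.message for r in caplog.records)
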