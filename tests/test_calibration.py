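"""Calibration tests: ELS objective, fitting, sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

import ketoflux as kf
from ketoflux.calibrate import (
    EmpiricalDataset,
    EstimationProblem,
    _Predictor,
    calibration_overlay,
    els_objective,
    fit,
    predict_at,
    sensitivity,
)
from ketoflux.simulate import SolverSettings


def make_problem(fixture, dataset, free, **kw):
    kw.setdefault("multistart", 1)
    kw.setdefault("seed", 1)
    return EstimationProblem(fixture=fixture, dataset=dataset, free_parameters=free, **kw)


class TestObjective:
    def test_perfect_fit_with_unit_variance_is_zero(self, fixture, noise_free_dataset):
        """With a+b·y = 1 for every point, residuals 0 give sum(ln 1) = 0."""
        data = noise_free_dataset.data.copy()
        prob = make_problem(
            fixture,
            EmpiricalDataset(data, lloq_mM=0.0),
            {"gut.upper_proximal.passive_k.ester": (0.2, 3.0)},
            variance_additive=1.0,
            variance_proportional=0.0,
            solver=SolverSettings(rtol=1e-8, atol=1e-10),
        )
        truth = fixture.get("gut.upper_proximal.passive_k.ester")
        assert els_objective([truth], prob) == pytest.approx(0.0, abs=1e-4)

    def test_doubling_residuals_increases_objective(self, fixture, noise_free_dataset):
        data1 = noise_free_dataset.data.copy()
        data2 = data1.copy()
        pred = data1["mean_mM"].to_numpy()
        data1["mean_mM"] = pred * 1.05  # residual 5% of the curve
        data2["mean_mM"] = pred * 1.10  # doubled residual
        free = {"gut.upper_proximal.passive_k.ester": (0.2, 3.0)}
        truth = [1.0]
        o1 = els_objective(truth, make_problem(fixture, EmpiricalDataset(data1), free))
        o2 = els_objective(truth, make_problem(fixture, EmpiricalDataset(data2), free))
        assert o2 > o1

    def test_minimum_at_data_generating_parameters(self, fixture, noise_free_dataset):
        """Grid search around the truth: no perturbed value beats it."""
        free = {"gut.upper_proximal.passive_k.ester": (0.2, 3.0)}
        prob = make_problem(fixture, noise_free_dataset, free)
        predictor = _Predictor(prob)
        truth = fixture.get("gut.upper_proximal.passive_k.ester")
        at_truth = els_objective([truth], prob, predictor)
        for factor in (0.7, 0.9, 0.97, 1.03, 1.1, 1.3):
            assert at_truth <= els_objective([truth * factor], prob, predictor) + 1e-9

    def test_invariant_to_observation_order(self, fixture, noise_free_dataset):
        free = {"gut.upper_proximal.passive_k.ester": (0.2, 3.0)}
        shuffled = noise_free_dataset.data.sort_values(
            ["dose_mg_per_kg", "time_h"], ascending=[False, True]
        ).reset_index(drop=True)
        o1 = els_objective([1.0], make_problem(fixture, noise_free_dataset, free))
        o2 = els_objective([1.0], make_problem(fixture, EmpiricalDataset(shuffled), free))
        assert o1 == pytest.approx(o2, rel=1e-12)

    def test_out_of_bounds_rejected(self, fixture, noise_free_dataset):
        prob = make_problem(fixture, noise_free_dataset, {"feedback.ic50": (1.0, 20.0)})
        with pytest.raises(ValueError, match="outside bounds"):
            els_objective([25.0], prob)

    def test_empty_free_set_rejected(self, fixture, noise_free_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            make_problem(fixture, noise_free_dataset, {})


class TestFit:
    def test_one_parameter_recovery_noise_free(self, fixture, noise_free_dataset):
        truth = fixture.get("gut.upper_proximal.passive_k.ester")
        prob = make_problem(
            fixture, noise_free_dataset, {"gut.upper_proximal.passive_k.ester": (0.2, 3.0)},
            multistart=2, seed=3,
        )
        res = fit(prob)
        est = res.estimates["gut.upper_proximal.passive_k.ester"]
        assert abs(est - truth) / truth < 0.01

    def test_deterministic_given_seed(self, fixture, noise_free_dataset):
        prob = make_problem(
            fixture, noise_free_dataset, {"feedback.ic50": (1.0, 20.0)}, multistart=2, seed=11
        )
        r1 = fit(prob)
        r2 = fit(prob)
        assert r1.estimates == r2.estimates
        assert r1.objective == r2.objective


class TestSensitivity:
    def test_blood_volume_elasticity_is_unity(self, fixture):
        """Concentration = amount / volume, so the volume elasticity of the
        blood BHB curve is -1 in magnitude everywhere."""
        table = sensitivity(
            fixture, ["physiology.blood_volume_L"], t_grid=kf.default_grid(4.0, 0.2)
        )
        assert table.loc[0, "rms_sensitivity"] == pytest.approx(1.0, rel=1e-3)

    def test_gated_off_parameter_has_zero_sensitivity(self, fixture):
        """A carrier with zero capacity contributes nothing, so its km is
        inert and the absorption-relevant ranking places it last."""
        fx = fixture.with_overrides({"gut.lower_proximal.apical_smct1.vmax": 0.0})
        table = sensitivity(
            fx,
            ["gut.lower_proximal.apical_smct1.km", "gut.upper_proximal.passive_k.ester"],
            t_grid=kf.default_grid(4.0, 0.2),
        )
        km_row = table[table.parameter == "gut.lower_proximal.apical_smct1.km"]
        assert km_row["rms_sensitivity"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table.iloc[0]["parameter"] == "gut.upper_proximal.passive_k.ester"

    def test_step_refinement_stable(self, fixture):
        """Halving the finite-difference step moves each RMS elasticity by
        far less than 1%: the curve is smooth in the parameters."""
        grid = kf.default_grid(4.0, 0.2)
        params = ["gut.upper_proximal.passive_k.ester", "feedback.ic50"]
        t1 = sensitivity(fixture, params, t_grid=grid, rel_step=0.01).set_index("parameter")
        t2 = sensitivity(fixture, params, t_grid=grid, rel_step=0.005).set_index("parameter")
        for p in params:
            a, b = t1.loc[p, "rms_sensitivity"], t2.loc[p, "rms_sensitivity"]
            assert abs(a - b) / b < 0.01

    def test_zero_parameter_uses_one_sided_difference(self, fixture):
        fx = fixture.with_overrides({"excretion.renal_bhb_k": 0.0})
        with pytest.warns(UserWarning, match="one-sided"):
            sensitivity(fx, ["excretion.renal_bhb_k"], t_grid=kf.default_grid(2.0, 0.5))


class TestOverlay:
    def test_noise_free_round_trip_residuals_zero(self, fixture, noise_free_dataset):
        _, table, frac = calibration_overlay(fixture, noise_free_dataset, make_figure=False)
        assert np.allclose(table["residual_mM"], 0.0, atol=1e-6)
        assert frac == 1.0

    def test_predictions_equal_means_flagged_within_sem(self, fixture, noise_free_dataset):
        table = predict_at(fixture, noise_free_dataset)
        fake = noise_free_dataset.data.copy()
        fake["mean_mM"] = table["prediction_mM"].to_numpy()
        fake["sem_mM"] = 0.05
        _, t2, frac = calibration_overlay(fixture, EmpiricalDataset(fake), make_figure=False)
        assert frac == 1.0

    def test_overlay_figure_has_one_panel_per_dose(self, fixture, noise_free_dataset):
        fig, _, _ = calibration_overlay(fixture, noise_free_dataset, make_figure=True)
        assert len(fig.axes) == len(noise_free_dataset.doses)


class TestDatasetValidation:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            EmpiricalDataset(pd.DataFrame({"time_h": [0.0]}))

    def test_negative_sem_rejected(self, noise_free_dataset):
        bad = noise_free_dataset.data.copy()
        bad.loc[0, "sem_mM"] = -0.1
        with pytest.raises(ValueError, match="SEM"):
            EmpiricalDataset(bad)

    def test_csv_round_trip(self, noise_free_dataset, tmp_path):
        path = tmp_path / "data.csv"
        noise_free_dataset.to_csv(path)
        loaded = EmpiricalDataset.from_csv(path, lloq_mM=0.1)
        pd.testing.assert_frame_equal(loaded.data, noise_free_dataset.data)
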