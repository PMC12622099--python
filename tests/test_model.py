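"""Brain-age fitting, bias correction, deltas: closed-form and leakage checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainage_influence import (
    AgeModelSpec,
    BrainAgeModel,
    fit_age_model,
    fit_bias_correction,
)
from conftest import make_cohort, single_feature_cohort

SPEC = AgeModelSpec(feature_set=("f",), regressor="linear", n_folds=5, seed=0)


class TestFitAgeModel:
    def test_perfect_predictor_has_zero_mae(self):
        c = single_feature_cohort(100, seed=0, noise_sd=0.0)
        res = fit_age_model(c, SPEC)
        assert res.mae_uncorrected <= 0.01

    def test_gaussian_noise_mae_matches_closed_form(self):
        """Residual ~ N(0, 4): E|residual| = 4 * sqrt(2/pi) ≈ 3.19 years."""
        c = single_feature_cohort(1000, seed=1, noise_sd=4.0)
        res = fit_age_model(c, SPEC)
        expected = 4.0 * np.sqrt(2.0 / np.pi)
        assert res.mae_uncorrected == pytest.approx(expected, rel=0.10)

    def test_repeat_fit_is_bit_identical(self):
        c = single_feature_cohort(200, seed=2, noise_sd=2.0)
        a, b = fit_age_model(c, SPEC), fit_age_model(c, SPEC)
        assert (a.oof_predictions == b.oof_predictions).all()
        assert a.mae_uncorrected == b.mae_uncorrected
        assert a.bias_coefficients == b.bias_coefficients

    def test_every_control_has_one_oof_prediction(self):
        c = single_feature_cohort(97, seed=3, noise_sd=2.0)
        res = fit_age_model(c, SPEC)
        assert sorted(res.oof_predictions.index) == sorted(c.subject_ids)
        assert res.oof_predictions.notna().all()

    def test_non_control_labels_rejected(self):
        c = make_cohort([70, 71, 72], ["CN", "AD", "CN"], {"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="AD"):
            fit_age_model(c, AgeModelSpec(("f",), n_folds=2))

    def test_fewer_controls_than_folds_rejected(self):
        c = single_feature_cohort(3, seed=4)
        with pytest.raises(ValueError, match="n_folds"):
            fit_age_model(c, SPEC)

    def test_fold_scaler_uses_training_subjects_only(self):
        """Leakage guard: each fold's scaler mean equals the mean of that
        fold's training subjects, not of the whole cohort."""
        c = single_feature_cohort(40, seed=5, noise_sd=1.0)
        spec = AgeModelSpec(("f",), n_folds=2, seed=0)
        res = fit_age_model(c, spec)
        x = c.features()["f"].to_numpy()
        for fold, pipe in enumerate(res.fold_models):
            train_mask = (res.fold_assignments != fold).to_numpy()
            expected_mean = x[train_mask].mean()
            assert pipe.named_steps["scaler"].mean_[0] == pytest.approx(expected_mean)
            assert expected_mean != pytest.approx(x.mean(), abs=1e-12)

    @pytest.mark.parametrize("regressor", ["linear", "ridge", "svr"])
    def test_all_regressors_learn_noiseless_feature(self, regressor):
        c = single_feature_cohort(300, seed=6, noise_sd=0.0)
        spec = AgeModelSpec(("f",), regressor=regressor, n_folds=5, seed=0)
        res = fit_age_model(c, spec)
        assert res.mae_uncorrected < 0.5

    def test_mae_computed_before_bias_correction(self):
        """mae_uncorrected equals mean |oof − age| regardless of the
        correction coefficients."""
        c = single_feature_cohort(300, seed=7, noise_sd=3.0)
        res = fit_age_model(c, SPEC)
        manual = float(
            np.mean(np.abs(res.oof_predictions.loc[c.subject_ids] - c.ages))
        )
        assert res.mae_uncorrected == pytest.approx(manual, abs=1e-12)


class TestBiasCorrection:
    def test_identity_predictions_give_identity_fit(self):
        ages = np.linspace(50, 90, 50)
        a, b = fit_bias_correction(ages, ages)
        assert (a, b) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-9))

    def test_exact_linear_shrinkage_recovered(self):
        """Regression-to-the-mean pattern ŷ = 0.5·y + 30 recovered exactly."""
        ages = np.linspace(50, 90, 60)
        a, b = fit_bias_correction(0.5 * ages + 30.0, ages)
        assert a == pytest.approx(0.5, abs=1e-9)
        assert b == pytest.approx(30.0, abs=1e-9)

    def test_noisy_coefficients_recovered_within_sampling_error(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(50, 90, 2000)
        preds = 0.7 * ages + 20.0 + rng.normal(0, 2.0, 2000)
        a, b = fit_bias_correction(preds, ages)
        assert a == pytest.approx(0.7, abs=0.02)
        assert b == pytest.approx(20.0, abs=1.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_bias_correction([70.0, 71.0, 72.0], [60.0, 60.0, 60.0])
        with pytest.raises(ValueError):
            fit_bias_correction([70.0, 71.0], [60.0, 61.0])


class TestComputeDeltas:
    def _fitted(self, n=300, seed=9, noise=3.0):
        c = single_feature_cohort(n, seed=seed, noise_sd=noise)
        return c, fit_age_model(c, SPEC)

    def test_delta_arithmetic_identity_correction(self):
        """(a,b) = (1,0): delta is simply ŷ − y."""
        c, res = self._fitted()
        res.bias_coefficients = (1.0, 0.0)
        d = res.compute_deltas(c, use_oof=True)
        expected = res.oof_predictions.loc[c.subject_ids] - c.ages
        assert np.allclose(d["delta"], expected)

    def test_delta_arithmetic_shrinkage_correction(self):
        """ŷ=65, y=70 under (a,b)=(0.5,30): corrected age 70, delta 0."""
        c, res = self._fitted(n=10, noise=0.0)
        res.bias_coefficients = (0.5, 30.0)
        res.oof_predictions.loc[:] = 0.5 * c.ages.to_numpy() + 30.0
        d = res.compute_deltas(c, use_oof=True)
        assert np.allclose(d["delta"], 0.0, atol=1e-9)

    def test_corrected_control_deltas_uncorrelated_with_age(self):
        """The purpose of the correction: oof delta-on-age slope ≈ 0."""
        c, res = self._fitted(n=1000, seed=10, noise=4.0)
        d = res.compute_deltas(c, use_oof=True)
        slope = stats.linregress(d["age"], d["delta"]).slope
        assert abs(slope) <= 0.02

    def test_alternative_correction_also_zeroes_slope(self):
        c = single_feature_cohort(1000, seed=11, noise_sd=4.0)
        spec = AgeModelSpec(("f",), n_folds=5, seed=0, bias_correction="delta_on_age")
        res = fit_age_model(c, spec)
        d = res.compute_deltas(c, use_oof=True)
        slope = stats.linregress(d["age"], d["delta"]).slope
        assert abs(slope) <= 0.02

    def test_oof_for_non_control_subject_rejected(self):
        c, res = self._fitted(n=50)
        stranger = make_cohort([70.0], ["AD"], {"f": [70.0]}, ids=["ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            res.compute_deltas(stranger, use_oof=True)

    def test_zero_slope_correction_rejected(self):
        c, res = self._fitted(n=50)
        res.bias_coefficients = (0.0, 10.0)
        with pytest.raises(ZeroDivisionError):
            res.compute_deltas(c, use_oof=True)

    def test_external_group_scored_with_full_model(self):
        """Non-control subjects get finite deltas via the refit pipeline."""
        c, res = self._fitted(n=200, noise=2.0)
        rng = np.random.default_rng(12)
        ages = rng.uniform(55, 85, 30)
        group = make_cohort(
            ages, ["AD"] * 30, {"f": ages + rng.normal(0, 2, 30)},
            ids=[f"AD{i}" for i in range(30)],
        )
        d = res.compute_deltas(group, use_oof=False)
        assert np.isfinite(d["delta"]).all()
        assert list(d.index) == group.subject_ids


class TestResultsInterface:
    def test_summary_reports_key_quantities(self):
        c = single_feature_cohort(100, seed=13, noise_sd=2.0)
        res = fit_age_model(c, SPEC)
        text = res.summary()
        assert "MAE" in text and "bias correction" in text
        assert f"{res.mae_uncorrected:.3f}" in text

    def test_json_sidecar_round_trips(self, tmp_path):
        import json

        c = single_feature_cohort(60, seed=14, noise_sd=2.0)
        res = fit_age_model(c, SPEC)
        p = res.to_json(tmp_path / "model.json")
        doc = json.loads(p.read_text())
        assert doc["mae_uncorrected"] == res.mae_uncorrected
        assert len(doc["fold_assignments"]) == 60

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AgeModelSpec(feature_set=())
        with pytest.raises(ValueError):
            AgeModelSpec(("f",), n_folds=1)
        with pytest.raises(ValueError):
            AgeModelSpec(("f",), regressor="forest")
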