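"""Latent-composite screening: PDO arithmetic, ML refit, fit indices."""

import numpy as np
import pandas as pd
import pytest

from omenscreen.cohort import FEATURES
from omenscreen.sem import (
    PUBLISHED_LOADINGS_BIO,
    PUBLISHED_LOADINGS_EYE,
    PdoModel,
    SemSpec,
    calibrate,
    compute_pdo,
    default_sem_spec,
    fit_indices,
    fit_sem,
    published_weights,
    screen_cohort,
    standardize_features,
)
from omenscreen.synthetic import (
    DEFAULT_FACTOR_LOADINGS,
    generate_factor_cohort,
)


def calibrated_published(standardization=None, bounds=(-2.0, 2.0), threshold=0.3125):
    std = standardization or {f: (0.0, 1.0) for f in FEATURES}
    base = published_weights()
    return PdoModel(
        lambda_bio=base.lambda_bio, lambda_eye=base.lambda_eye, rho=base.rho,
        standardization=std, bounds=bounds, threshold=threshold,
    )


class TestStandardize:
    def test_unit_spaced_column(self):
        frame = pd.DataFrame({f: [1.0, 2.0, 3.0] for f in FEATURES})
        z, params = standardize_features(frame)
        assert list(z["alpha"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert params["alpha"] == (2.0, 1.0)

    def test_training_mean_maps_to_zero(self, cohort134):
        z, params = standardize_features(cohort134)
        mean, sd = params["ecg"]
        assert (mean - params["ecg"][0]) / sd == 0.0
        assert z["ecg"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_names_feature(self):
        frame = pd.DataFrame({f: [1.0, 1.0, 1.0] for f in FEATURES})
        with pytest.raises(ValueError, match="alpha"):
            standardize_features(frame)


class TestPublishedWeights:
    def test_reported_values(self):
        m = published_weights()
        assert m.lambda_bio["delta"] == 0.511
        assert m.lambda_eye["lpd"] == -0.012
        assert m.rho == (1.000, 0.068)
        assert m.threshold == 0.3125
        assert not m.is_calibrated()


class TestComputePdo:
    def test_zero_input_gives_zero_raw(self):
        model = calibrated_published()
        feats = {f: 0.0 for f in FEATURES}
        feats["driver_id"] = "d"
        assert compute_pdo(feats, model).raw_pdo == 0.0

    def test_all_ones_matches_weight_sums(self):
        # sum(lambda_bio) = 1.362, sum(lambda_eye) = 0.031
        model = calibrated_published()
        feats = {f: 1.0 for f in FEATURES}
        feats["driver_id"] = "d"
        r = compute_pdo(feats, model)
        assert r.raw_pdo == pytest.approx(1.0 * 1.362 + 0.068 * 0.031)
        assert r.raw_pdo == pytest.approx(1.364108)

    def test_boundary_score_classifies_d2(self):
        # raw chosen so the normalized score is exactly the threshold
        model = calibrated_published(bounds=(0.0, 1.0))
        sums = 1.362 + 0.068 * 0.031
        feats = {f: 0.3125 / sums for f in FEATURES}
        feats["driver_id"] = "d"
        r = compute_pdo(feats, model)
        assert r.normalized_pdo == pytest.approx(0.3125)
        assert r.predicted == "D2"

    def test_missing_feature_listed(self):
        model = calibrated_published()
        feats = {f: 0.0 for f in FEATURES if f != "gv"}
        with pytest.raises(ValueError, match="gv"):
            compute_pdo(feats, model)

    def test_uncalibrated_model_rejected(self):
        feats = {f: 0.0 for f in FEATURES}
        with pytest.raises(ValueError, match="calibrat"):
            compute_pdo(feats, published_weights())

    def test_monotone_in_signed_weights(self):
        model = calibrated_published()
        base = {f: 0.0 for f in FEATURES}
        up_delta = dict(base, delta=1.0)
        up_gamma = dict(base, gamma=1.0)
        raw0 = compute_pdo(dict(base, driver_id="d"), model).raw_pdo
        assert compute_pdo(dict(up_delta, driver_id="d"), model).raw_pdo > raw0
        assert compute_pdo(dict(up_gamma, driver_id="d"), model).raw_pdo < raw0


class TestFitSem:
    def test_recovers_generating_loadings(self):
        cohort = generate_factor_cohort(
            2500, 2500, seed=21, factor_corr=0.3,
            group_shift_bio=0.0, group_shift_eye=0.0,
        )
        z, _ = standardize_features(cohort)
        fit = fit_sem(z)
        for factor in fit.loadings:
            for ind, val in fit.loadings[factor].items():
                assert val == pytest.approx(DEFAULT_FACTOR_LOADINGS[ind], abs=0.05)
        assert fit.factor_corr == pytest.approx(0.3, abs=0.05)
        assert not fit.heywood

    def test_sign_anchoring_orients_loading_sums_positive(self):
        cohort = generate_factor_cohort(
            1000, 1000, seed=22, group_shift_bio=0.0, group_shift_eye=0.0
        )
        z, _ = standardize_features(cohort)
        fit = fit_sem(z)
        for factor, lams in fit.loadings.items():
            assert sum(lams.values()) >= 0

    def test_too_few_observations_rejected(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 9)), columns=FEATURES)
        with pytest.raises(ValueError, match="observations"):
            fit_sem(z)

    def test_standardized_loadings_bounded(self, cohort134):
        z, _ = standardize_features(cohort134)
        fit = fit_sem(z)
        for lams in fit.loadings.values():
            assert all(abs(v) <= 1.0 + 1e-9 for v in lams.values())


class TestFitIndices:
    def test_rmsea_closed_form(self):
        # chi2 = 2*df at N = 101, df = 10 -> RMSEA = 0.1
        from dataclasses import replace

        cohort = generate_factor_cohort(
            600, 600, seed=23, group_shift_bio=0.0, group_shift_eye=0.0
        )
        z, _ = standardize_features(cohort)
        fit = fit_sem(z)
        forged = replace(
            fit, discrepancy=2 * 10 / 100.0, n_obs=101, n_free=fit.n_free,
        )
        forged = replace(forged, df=10)
        fi = fit_indices(forged)
        assert fi.rmsea == pytest.approx(np.sqrt(10 / (10 * 100.0)))
        assert fi.chi2_per_df == pytest.approx(2.0)

    def test_good_model_fits_well(self):
        cohort = generate_factor_cohort(
            2000, 2000, seed=24, group_shift_bio=0.0, group_shift_eye=0.0
        )
        z, _ = standardize_features(cohort)
        fi = fit_indices(fit_sem(z))
        assert fi.rmsea < 0.05
        assert fi.cfi > 0.95 and fi.nfi > 0.9 and fi.gfi > 0.95

    def test_zero_discrepancy_is_perfect_fit(self):
        from dataclasses import replace

        cohort = generate_factor_cohort(
            600, 600, seed=25, group_shift_bio=0.0, group_shift_eye=0.0
        )
        z, _ = standardize_features(cohort)
        fit = replace(fit_sem(z), discrepancy=0.0)
        fi = fit_indices(fit)
        assert fi.chi2 == 0.0 and fi.cfi == 1.0 and fi.rmsea == 0.0


class TestCalibrate:
    def test_published_mode_keeps_reported_threshold(self, cohort134):
        model = calibrate(cohort134, mode="published")
        assert model.threshold == 0.3125
        assert model.lambda_bio == PUBLISHED_LOADINGS_BIO
        assert model.lambda_eye == PUBLISHED_LOADINGS_EYE
        assert model.is_calibrated()

    def test_training_scores_attain_bounds(self, cohort134):
        model = calibrate(cohort134, mode="published")
        scores = [r.normalized_pdo for r in screen_cohort(cohort134, model)]
        assert min(scores) == 0.0 and max(scores) == 1.0
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_deterministic_given_cohort_and_mode(self, cohort134):
        a = [r.normalized_pdo for r in screen_cohort(cohort134, calibrate(cohort134))]
        b = [r.normalized_pdo for r in screen_cohort(cohort134, calibrate(cohort134))]
        assert a == b

    def test_refit_threshold_splits_separated_classes(self):
        cohort = generate_factor_cohort(60, 60, seed=26, group_shift_bio=10.0)
        model = calibrate(cohort, mode="refit")
        scores = np.array([r.normalized_pdo for r in screen_cohort(cohort, model)])
        labels = np.array(cohort.labels())
        hi_d1 = scores[labels == "D1"].max()
        lo_d2 = scores[labels == "D2"].min()
        assert hi_d1 < lo_d2  # premise: training scores perfectly separated
        assert hi_d1 < model.threshold <= lo_d2

    def test_refit_rho2_magnitude_below_fixed_rho1(self):
        cohort = generate_factor_cohort(400, 400, seed=27)
        model = calibrate(cohort, mode="refit")
        assert model.rho[0] == 1.0
        assert abs(model.rho[1]) < 1.0

    def test_single_class_cohort_rejected(self, cohort134):
        with pytest.raises(ValueError):
            calibrate(cohort134.group("D2"))

    def test_ablated_single_feature_subset(self, cohort134):
        model = calibrate(cohort134, mode="refit", features=("ecg",))
        assert model.lambda_bio == {"ecg": 1.0} and model.lambda_eye == {}

    def test_held_out_scores_clipped(self, cohort134):
        model = calibrate(cohort134, mode="published")
        extreme = {f: 1e6 for f in FEATURES}
        extreme["driver_id"] = "x"
        assert compute_pdo(extreme, model).normalized_pdo == 1.0


class TestSemSpec:
    def test_indicator_in_two_factors_rejected(self):
        with pytest.raises(ValueError):
            SemSpec(factors={"a": ("alpha", "beta"), "b": ("beta", "gv")})

    def test_default_structure(self):
        spec = default_sem_spec()
        assert spec.factors["bioelectrical"] == (
            "alpha", "beta", "theta", "delta", "gamma", "ecg"
        )
        assert spec.factors["eye_movement"] == ("gv", "lpd", "rpd")
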