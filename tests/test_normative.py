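"""GP normative models: posterior correctness, calibration, scoring rules."""

import json

import numpy as np
import pandas as pd
import pytest

from neonorm import fit_region_model, generate_normative_cohort
from neonorm.normative import (
    AtypicalityProfiles,
    NormativeModel,
    _kernel,
    _scale_covariates,
)

FIXED_THETA = np.log([0.6, 1.2, 0.8, 1.5, 0.3, 0.1])


def _toy_cohort(n=30, seed=0, slope=5.0, noise=2.0):
    rng = np.random.default_rng(seed)
    pma = np.linspace(37.0, 45.0, n)
    days = rng.integers(1, 15, size=n).astype(float)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    vol = 100.0 + slope * (pma - 40.0) + 0.5 * days + noise * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "pma_scan": pma,
            "postnatal_days": days,
            "sex": sex,
            "vol_cortical_gm": vol,
        }
    )


def _dense_gp_oracle(model, pma, days, sex):
    """Naive dense-matrix GP posterior, written from the textbook formulas."""
    sf2, l1, l2, l3, sl2, sn2 = np.exp(model.log_theta)
    Xt = np.column_stack(
        [
            (model.X_raw["pma_scan"].to_numpy() - 40.0) / 4.0,
            model.X_raw["postnatal_days"].to_numpy() / 7.0,
            model.X_raw["sex"].to_numpy(dtype=float) - 0.5,
        ]
    )
    male = (np.asarray(sex) == "male").astype(float) if np.asarray(sex).dtype.kind in "UO" else np.asarray(sex, float)
    Xq = np.column_stack(
        [(np.atleast_1d(pma) - 40.0) / 4.0, np.atleast_1d(days) / 7.0, male - 0.5]
    )

    def k(A, B):
        ls = np.array([l1, l2, l3])
        out = np.empty((len(A), len(B)))
        for i in range(len(A)):
            for j in range(len(B)):
                d = (A[i] - B[j]) / ls
                out[i, j] = sf2 * np.exp(-0.5 * d @ d) + sl2 * (A[i] @ B[j])
        return out

    n = len(Xt)
    K = k(Xt, Xt) + (sn2 + model.jitter) * np.eye(n)
    Kinv = np.linalg.inv(K)
    y = (model.y_raw - model.y_mean) / model.y_sd
    Ks = k(Xq, Xt)
    mean = Ks @ Kinv @ y
    var = np.diag(k(Xq, Xq)) + sn2 - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return model.y_mean + model.y_sd * mean, model.y_sd * np.sqrt(var)


class TestPosterior:
    def test_two_point_closed_form(self):
        """Posterior at a query matches explicit 2x2 GP algebra."""
        cohort = _toy_cohort(n=30).iloc[:20]  # fit requires >= 20 rows
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        # hand-build the 2x2 case from the first two subjects only
        m2 = NormativeModel(
            region="cortical_gm",
            log_theta=FIXED_THETA,
            X_raw=model.X_raw.iloc[:2].reset_index(drop=True),
            y_raw=model.y_raw[:2],
            y_mean=float(model.y_raw[:2].mean()),
            y_sd=float(model.y_raw[:2].std()),
            jitter=0.0,
        )
        Xs = _scale_covariates(
            m2.X_raw["pma_scan"], m2.X_raw["postnatal_days"], m2.X_raw["sex"]
        )
        sf2, l1, l2, l3, sl2, sn2 = np.exp(FIXED_THETA)
        ls = np.array([l1, l2, l3])

        def kf(a, b):
            d = (a - b) / ls
            return sf2 * np.exp(-0.5 * d @ d) + sl2 * (a @ b)

        q = np.array([(41.5 - 40.0) / 4.0, 4.0 / 7.0, 0.5])
        K = np.array(
            [[kf(Xs[0], Xs[0]) + sn2, kf(Xs[0], Xs[1])],
             [kf(Xs[1], Xs[0]), kf(Xs[1], Xs[1]) + sn2]]
        )
        ks = np.array([kf(q, Xs[0]), kf(q, Xs[1])])
        y = m2.y_std
        det = K[0, 0] * K[1, 1] - K[0, 1] * K[1, 0]
        Kinv = np.array([[K[1, 1], -K[0, 1]], [-K[1, 0], K[0, 0]]]) / det
        mean_exp = m2.y_mean + m2.y_sd * (ks @ Kinv @ y)
        var_exp = kf(q, q) + sn2 - ks @ Kinv @ ks
        sd_exp = m2.y_sd * np.sqrt(var_exp)

        mean, sd = m2.predict(41.5, 4.0, "male")
        assert mean == pytest.approx(mean_exp, rel=1e-10)
        assert sd == pytest.approx(sd_exp, rel=1e-10)

    def test_matches_dense_oracle(self):
        """Posterior mean/SD equal a naive dense solve to 1e-8 (<=50 points)."""
        cohort = _toy_cohort(n=50, seed=3)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        rng = np.random.default_rng(0)
        pma = rng.uniform(37, 45, 25)
        days = rng.integers(0, 20, 25).astype(float)
        sex = np.where(rng.random(25) < 0.5, "male", "female")
        mean, sd = model.predict(pma, days, sex)
        mean_o, sd_o = _dense_gp_oracle(model, pma, days, sex)
        scale = model.y_sd  # compare on the standardized scale
        assert np.max(np.abs(mean - mean_o)) / scale < 1e-8
        assert np.max(np.abs(sd - sd_o)) / scale < 1e-8

    def test_matches_sklearn_gp(self):
        """Independent cross-check against scikit-learn's exact GP."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (
            RBF,
            ConstantKernel,
            DotProduct,
            WhiteKernel,
        )

        cohort = _toy_cohort(n=40, seed=5)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        sf2, l1, l2, l3, sl2, sn2 = np.exp(FIXED_THETA)
        kernel = (
            ConstantKernel(sf2, "fixed") * RBF([l1, l2, l3], "fixed")
            + ConstantKernel(sl2, "fixed") * DotProduct(sigma_0=0.0, sigma_0_bounds="fixed")
            + WhiteKernel(sn2, "fixed")
        )
        Xs = _scale_covariates(
            model.X_raw["pma_scan"], model.X_raw["postnatal_days"], model.X_raw["sex"]
        )
        gp = GaussianProcessRegressor(kernel=kernel, alpha=model.jitter).fit(
            Xs, model.y_std
        )
        pma = np.linspace(37.5, 44.5, 15)
        days = np.full(15, 5.0)
        sex = np.array(["male"] * 15)
        mean, sd = model.predict(pma, days, sex)
        mu_sk, sd_sk = gp.predict(_scale_covariates(pma, days, sex), return_std=True)
        np.testing.assert_allclose(mean, model.y_mean + model.y_sd * mu_sk, rtol=1e-8)
        np.testing.assert_allclose(sd, model.y_sd * sd_sk, rtol=1e-6)

    def test_noise_free_linear_interpolation(self):
        """With the noise floor disabled and exactly linear targets, the fit
        reproduces its training data."""
        cohort = _toy_cohort(n=25, noise=0.0)
        model = fit_region_model(
            cohort, "cortical_gm", noise_floor=None, n_restarts=3, seed=0
        )
        pred, _ = model.predict(
            cohort["pma_scan"], cohort["postnatal_days"], cohort["sex"]
        )
        np.testing.assert_allclose(pred, cohort["vol_cortical_gm"], atol=1e-3)

    def test_permutation_invariance(self):
        cohort = _toy_cohort(n=40, seed=7)
        perm = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m1 = fit_region_model(cohort, "cortical_gm", n_restarts=2, seed=0)
        m2 = fit_region_model(perm, "cortical_gm", n_restarts=2, seed=0)
        pma, days, sex = np.array([39.0, 42.0]), np.array([3.0, 8.0]), np.array(["male", "female"])
        p1, s1 = m1.predict(pma, days, sex)
        p2, s2 = m2.predict(pma, days, sex)
        np.testing.assert_allclose(p1, p2, rtol=1e-6)
        np.testing.assert_allclose(s1, s2, rtol=1e-6)

    def test_predictive_sd_has_noise_floor(self):
        cohort = _toy_cohort(n=30)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        sn = np.sqrt(np.exp(FIXED_THETA[5]))
        _, sd = model.predict(np.linspace(37, 45, 20), np.full(20, 4.0), ["male"] * 20)
        assert np.all(sd >= sn * model.y_sd * (1 - 1e-12))

    def test_sd_grows_outside_training_window(self):
        cohort = _toy_cohort(n=30)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        _, sd_in = model.predict(45.0, 4.0, "male")
        with pytest.warns(UserWarning, match="extrapolating"):
            _, sd_out = model.predict(47.0, 4.0, "male")
        assert sd_out >= sd_in


class TestAtypicalityIndex:
    def test_definition(self):
        cohort = _toy_cohort(n=30)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        pred, sd = model.predict(40.0, 5.0, "female")
        assert model.atypicality_index(pred, 40.0, 5.0, "female") == pytest.approx(0.0, abs=1e-12)
        assert model.atypicality_index(pred + 2 * sd, 40.0, 5.0, "female") == pytest.approx(2.0)
        # smaller-than-expected volume gives negative z
        assert model.atypicality_index(pred - sd, 40.0, 5.0, "female") < 0

    def test_missing_volume_is_absent_not_zero(self):
        cohort = _toy_cohort(n=30)
        model = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        z = model.atypicality_index(np.array([np.nan]), [40.0], [5.0], ["male"])
        assert np.isnan(z[0])

    def test_scale_equivariance(self):
        """Multiplying a region's volumes by any constant leaves z unchanged."""
        cohort = _toy_cohort(n=30, seed=9)
        scaled = cohort.copy()
        scaled["vol_cortical_gm"] *= 3.7
        m1 = fit_region_model(cohort, "cortical_gm", fixed_theta=FIXED_THETA)
        m2 = fit_region_model(scaled, "cortical_gm", fixed_theta=FIXED_THETA)
        z1 = m1.atypicality_index(110.0, 41.0, 6.0, "male")
        z2 = m2.atypicality_index(110.0 * 3.7, 41.0, 6.0, "male")
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_holdout_z_calibrated_cross_validated(self, params, normative_cohort):
        """5-fold held-out normative subjects score z ~ N(0, 1)."""
        regions = ["cortical_gm", "ventricles", "thalamus_l", "ttv"]
        folds = np.arange(len(normative_cohort)) % 5
        zs = []
        for fold in range(5):
            train = normative_cohort[folds != fold]
            test = normative_cohort[folds == fold]
            for region in regions:
                model = fit_region_model(
                    train, region, log_transform=region == "ventricles",
                    n_restarts=3, seed=fold, maxiter=120,
                )
                col = "ttv" if region == "ttv" else f"vol_{region}"
                zs.append(
                    model.atypicality_index(
                        test[col].to_numpy(float),
                        test["pma_scan"].to_numpy(float),
                        test["postnatal_days"].to_numpy(float),
                        test["sex"].to_numpy(),
                    )
                )
        z = np.concatenate(zs)
        # sampling noise plus hyperparameter-estimation error across 20 fits
        assert np.mean(z) == pytest.approx(0.0, abs=0.1)
        assert np.std(z) == pytest.approx(1.0, abs=0.1)


class TestFlagsAndErrors:
    def test_extreme_flags_strict_inequality(self):
        z = pd.DataFrame(
            {"cortical_gm": [2.61, -2.6, 0.0, -2.75, np.nan]},
            index=pd.Index([f"s{i}" for i in range(5)], name="subject_id"),
        )
        prof = AtypicalityProfiles(z, threshold=2.6)
        flags = prof.flags["cortical_gm"]
        assert flags["s0"] == "extreme_positive"
        assert flags["s1"] == "none"  # -2.6 exactly: strict inequality
        assert flags["s2"] == "none"
        assert flags["s3"] == "extreme_negative"
        assert pd.isna(flags["s4"])
        assert prof.n_extreme_per_subject().tolist() == [1, 0, 0, 1, 0]

    def test_all_zero_profile_no_flags(self):
        z = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0]},
                         index=pd.Index(["x", "y"], name="subject_id"))
        prof = AtypicalityProfiles(z, threshold=2.6)
        assert (prof.flags == "none").all().all()

    def test_degenerate_pma_rejected(self):
        cohort = _toy_cohort(n=25)
        cohort["pma_scan"] = 40.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_region_model(cohort, "cortical_gm")

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_region_model(_toy_cohort(n=10), "cortical_gm")

    def test_unknown_region_rejected(self, normative_cohort):
        with pytest.raises(KeyError, match="valid regions"):
            fit_region_model(normative_cohort, "amygdala")

    def test_json_round_trip_reproduces_predictions(self):
        cohort = _toy_cohort(n=30)
        model = fit_region_model(cohort, "cortical_gm", n_restarts=2, seed=0)
        clone = NormativeModel.from_json(model.to_json())
        pma = np.linspace(37, 45, 9)
        days = np.full(9, 4.0)
        sex = ["female"] * 9
        p1, s1 = model.predict(pma, days, sex)
        p2, s2 = clone.predict(pma, days, sex)
        assert np.array_equal(p1, p2) and np.array_equal(s1, s2)


def test_kernel_is_psd_on_random_inputs(rng):
    X = rng.uniform(-1, 1, size=(30, 3))
    K = _kernel(FIXED_THETA, X, X) + np.exp(FIXED_THETA[5]) * np.eye(30)
    eig = np.linalg.eigvalsh(K)
    assert eig.min() > 0
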