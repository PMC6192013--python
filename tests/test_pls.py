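import numpy as np
import pytest

from procspec.dataset import PairedData
from procspec.plsmodel import (
    NIPALSPLS,
    fit_pls,
    lbo_cv,
    loo_cv,
    lv_scan,
    r2,
    rmse,
    validate_external,
)
from procspec.preprocess import MultiplicativeScatterCorrection

from conftest import make_linear_paired


def nipals_pls1_oracle(X, y, A):
    """Step-by-step NIPALS PLS1 reference written independently: explicit
    loops, no shortcuts; returns the prediction function pieces."""
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float).copy()
    x_mean, y_mean = X.mean(axis=0), y.mean()
    E, f = X - x_mean, y - y_mean
    W, P, q, T = [], [], [], []
    for _ in range(A):
        w = E.T @ f
        w = w / np.sqrt(np.sum(w**2))
        t = E @ w
        p = E.T @ t / (t @ t)
        qa = f @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - qa * t
        W.append(w), P.append(p), q.append(qa), T.append(t)
    W, P, q = np.array(W).T, np.array(P).T, np.array(q)
    B = W @ np.linalg.inv(P.T @ W) @ q
    return x_mean, y_mean, B, np.array(T).T


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.full(3, y.mean())
        assert r2(y, y_hat) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # SS_res = 1 + 1 = 2; SS_tot about mean(y)=1 is also 2, so R^2 = 0
        y, y_hat = np.array([0.0, 2.0]), np.array([1.0, 1.0])
        assert rmse(y, y_hat) == pytest.approx(1.0)
        assert r2(y, y_hat) == pytest.approx(0.0)
        # a prediction worse than the mean goes negative
        assert r2(y, np.array([2.0, 0.0])) == pytest.approx(-3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse(np.ones(3), np.ones(4))


class TestNIPALSFit:
    def test_single_factor_noise_free_exact(self, linear_paired):
        model = fit_pls(linear_paired.spectra, linear_paired.lod, n_components=1)
        y_hat = model.predict(linear_paired.spectra)
        assert rmse(linear_paired.lod, y_hat) < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_full_rank_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 12, 4
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        model = fit_pls(X, y, n_components=p)
        # OLS oracle on centered data
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        y_ols = y.mean() + (X - X.mean(axis=0)) @ beta
        np.testing.assert_allclose(model.predict(X), y_ols, atol=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_stepwise_nipals_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit_pls(X, y, n_components=3)
        x_mean, y_mean, B, T = nipals_pls1_oracle(X, y, 3)
        np.testing.assert_allclose(model.coef_, B, atol=1e-10)
        np.testing.assert_allclose(model.x_scores_, T, atol=1e-10)
        np.testing.assert_allclose(model.predict(X), y_mean + (X - x_mean) @ B,
                                   atol=1e-10)

    def test_agrees_with_sklearn_cross_check(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        ours = fit_pls(X, y, n_components=5).predict(X)
        theirs = sklearn_pls(n_components=5, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = fit_pls(X, y, n_components=6)
        G = model.x_scores_.T @ model.x_scores_
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_rank_exceeded_rejected(self):
        X = np.outer(np.arange(6.0), np.ones(4))  # rank 1 after centering
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, n_components=3)

    def test_degenerate_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(X, np.ones(6), n_components=1)

    def test_predict_grid_mismatch_rejected(self, linear_paired):
        model = fit_pls(linear_paired.spectra, linear_paired.lod, 1)
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(np.ones((2, linear_paired.spectra.shape[1] + 1)))

    def test_predict_constant_x_gives_training_mean(self, linear_paired):
        model = fit_pls(linear_paired.spectra, linear_paired.lod, 1)
        X0 = np.tile(model.x_mean_, (3, 1))
        np.testing.assert_allclose(model.predict(X0), model.y_mean_, atol=1e-10)

    def test_prediction_affine_in_x(self, linear_paired):
        model = fit_pls(linear_paired.spectra, linear_paired.lod, 1)
        rng = np.random.default_rng(5)
        Xa = rng.normal(size=(4, linear_paired.spectra.shape[1]))
        Xb = rng.normal(size=Xa.shape)
        lhs = model.predict((Xa + Xb) / 2)
        rhs = (model.predict(Xa) + model.predict(Xb)) / 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestCrossValidation:
    def test_loo_noise_free_single_factor(self, linear_paired):
        report = loo_cv(linear_paired, n_components=1)
        assert report.rmse < 1e-6
        assert len(report.predictions) == linear_paired.n_samples

    def test_loo_matches_explicit_loop_oracle(self):
        paired = make_linear_paired(n=8, p=5, noise=0.3, seed=4)
        report = loo_cv(paired, n_components=2)
        for i in range(8):
            mask = np.ones(8, dtype=bool)
            mask[i] = False
            model = fit_pls(paired.spectra[mask], paired.lod[mask], 2)
            expected = model.predict(paired.spectra[i][None, :])[0]
            assert report.predictions["predicted"].iloc[i] == pytest.approx(expected)

    def test_lbo_matches_explicit_loop_oracle(self):
        paired = make_linear_paired(n=12, p=5, n_batches=3, noise=0.3, seed=6)
        report = lbo_cv(paired, n_components=2)
        for bid in np.unique(paired.batch_ids):
            held = paired.batch_ids == bid
            model = fit_pls(paired.spectra[~held], paired.lod[~held], 2)
            expected = model.predict(paired.spectra[held])
            got = report.predictions.loc[
                report.predictions["batch_id"] == bid, "predicted"
            ].to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_lbo_fold_counts_sum_to_n(self):
        paired = make_linear_paired(n=12, n_batches=3, noise=0.2, seed=1)
        report = lbo_cv(paired, n_components=2)
        assert len(report.predictions) == 12
        assert set(report.predictions["batch_id"]) == set(paired.batch_ids)

    def test_lbo_single_batch_rejected(self):
        paired = make_linear_paired(n=8, n_batches=1, noise=0.1)
        with pytest.raises(ValueError, match="2 batches"):
            lbo_cv(paired, n_components=1)

    def test_msc_reference_refit_per_fold(self):
        """The fold-internal MSC reference must exclude the held-out sample:
        compare against an explicit loop that re-fits MSC by hand."""
        paired = make_linear_paired(n=9, p=12, noise=0.05, seed=2)
        spectra = np.abs(paired.spectra) + 5.0  # keep slopes well away from 0
        paired = PairedData(
            batch_ids=paired.batch_ids, sample_times=paired.sample_times,
            spectra=spectra, lod=paired.lod, wavelengths=paired.wavelengths,
        )
        report = loo_cv(paired, n_components=2,
                        chain=[MultiplicativeScatterCorrection()])
        from procspec.preprocess import msc
        for i in range(3):
            mask = np.ones(9, dtype=bool)
            mask[i] = False
            X_tr, ref = msc(paired.spectra[mask])
            X_te, _ = msc(paired.spectra[[i]], ref)
            model = fit_pls(X_tr, paired.lod[mask], 2)
            assert report.predictions["predicted"].iloc[i] == pytest.approx(
                model.predict(X_te)[0]
            )


class TestExternalValidation:
    def test_copy_of_calibration_matches_calibration_stats(self):
        calib = make_linear_paired(n=10, n_batches=2, noise=0.2, seed=7)
        valid = PairedData(
            batch_ids=np.array(["V"] * 10, dtype=object),
            sample_times=calib.sample_times,
            spectra=calib.spectra.copy(),
            lod=calib.lod.copy(),
            wavelengths=calib.wavelengths,
        )
        model, report = validate_external(calib, valid, n_components=2)
        y_hat = model.predict(calib.spectra)
        assert report.rmse == pytest.approx(rmse(calib.lod, y_hat))
        assert report.r2 == pytest.approx(r2(calib.lod, y_hat))

    def test_overlapping_batches_rejected(self):
        paired = make_linear_paired(n=8, n_batches=2, noise=0.1)
        with pytest.raises(ValueError, match="share batch"):
            validate_external(paired, paired, n_components=1)

    def test_simulated_campaign_split(self, small_campaign):
        from procspec.dataset import pair_campaign

        calib = pair_campaign(small_campaign,
                              batch_ids=small_campaign.ids_with_role("calibration"))
        valid = pair_campaign(small_campaign,
                              batch_ids=small_campaign.ids_with_role("validation"))
        model, report = validate_external(calib, valid, n_components=7)
        assert report.scheme == "external"
        assert len(report.predictions) == valid.n_samples
        assert report.r2 > 0.99


class TestLVScan:
    def test_table_has_requested_rows(self):
        paired = make_linear_paired(n=14, n_batches=3, noise=0.3, seed=9)
        table = lv_scan(paired, a_max=4, scheme="lbo")
        assert list(table["n_components"]) == [1, 2, 3, 4]

    def test_calibration_rmse_non_increasing(self):
        rng = np.random.default_rng(11)
        paired = make_linear_paired(n=20, p=8, noise=0.5, seed=11)
        table = lv_scan(paired, a_max=6, scheme="calibration")
        assert np.all(np.diff(table["rmse"]) <= 1e-10)

    def test_single_factor_plateaus_at_one(self):
        # one dominant factor + faint noise: the error curve is flat after A=1
        paired = make_linear_paired(n=15, p=6, noise=1e-4, seed=3)
        table = lv_scan(paired, a_max=3, scheme="calibration")
        assert table["rmse"].iloc[0] < 1e-3
        assert table["rmse"].iloc[2] <= table["rmse"].iloc[0] < table["rmse"].iloc[2] + 1e-3

    def test_scan_matches_direct_refits(self):
        paired = make_linear_paired(n=14, n_batches=3, noise=0.4, seed=13)
        table = lv_scan(paired, a_max=3, scheme="lbo")
        for a in (1, 2, 3):
            direct = lbo_cv(paired, n_components=a).rmse
            assert table["rmse"].iloc[a - 1] == pytest.approx(direct)

    def test_unknown_scheme_rejected(self, linear_paired):
        with pytest.raises(ValueError, match="scheme"):
            lv_scan(linear_paired, a_max=2, scheme="bootstrap")


class TestConservatism:
    def test_lbo_at_least_calibration_on_simulation(self, small_campaign):
        """Batch-wise validation is the conservative scheme: its error is
        above the calibration (resubstitution) error on simulated data."""
        from procspec.dataset import pair_campaign
        from procspec.plsmodel import calibration_fit

        paired = pair_campaign(small_campaign, smoother=15)
        _, _, calib = calibration_fit(paired, n_components=7)
        lbo = lbo_cv(paired, n_components=7)
        assert lbo.rmse >= calib.rmse
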