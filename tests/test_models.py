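import math

import numpy as np
import pandas as pd
import pytest

from pepqsar.encoding import PeptideRecord, ScalingParams, autoscale
from pepqsar.models import (
    f_statistic,
    fit_mlr,
    fit_pls,
    fit_rf,
    fit_svr,
    kfold_q2,
    loo_q2,
    r2_pearson,
    split_train_test,
    summarize,
)

from conftest import random_design


def nipals_pls1(X, y, n_components):
    """Direct NIPALS transcription for single-response PLS (oracle)."""
    X = X.copy().astype(float)
    y = y.copy().astype(float).reshape(-1, 1)
    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        w = X.T @ y
        w /= np.linalg.norm(w)
        t = X @ w
        tt = (t.T @ t).item()
        p = X.T @ t / tt
        q = (y.T @ t).item() / tt
        X = X - t @ p.T
        y = y - t * q
        W.append(w.ravel())
        P.append(p.ravel())
        Q.append(q)
        T.append(t.ravel())
    W, P = np.array(W).T, np.array(P).T
    beta = W @ np.linalg.solve(P.T @ W, np.array(Q))
    return beta


def scaling_for(y):
    y = np.asarray(y, dtype=float)
    return ScalingParams(
        mean=pd.Series(dtype=float),
        sd=pd.Series(dtype=float),
        y_mean=float(y.mean()),
        y_sd=float(y.std(ddof=1)),
    )


class TestSplit:
    def make(self, activities):
        from pepqsar.aaindex import STANDARD_RESIDUES

        res = STANDARD_RESIDUES
        return [
            PeptideRecord(
                sequence=f"{res[i % 20]}A{res[i // 20]}", activity=float(a)
            )
            for i, a in enumerate(activities)
        ]

    def test_91_records_give_31_test_60_train(self):
        rng = np.random.default_rng(0)
        train, test = split_train_test(self.make(rng.uniform(0, 2, 91)))
        assert len(train) == 60 and len(test) == 31
        assert all(p.subset_label == "train" for p in train)
        assert all(p.subset_label == "test" for p in test)

    def test_every_third_rank_goes_to_test(self):
        peptides = self.make([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        train, test = split_train_test(peptides)
        ordered = sorted(peptides, key=lambda p: -p.activity)
        assert test == [ordered[0], ordered[3]]
        assert len(train) == 4

    def test_three_records_most_active_is_test(self):
        peptides = self.make([0.1, 0.9, 0.5])
        train, test = split_train_test(peptides)
        assert len(test) == 1 and test[0].activity == 0.9

    def test_fewer_than_three_all_train_with_warning(self):
        with pytest.warns(UserWarning):
            train, test = split_train_test(self.make([0.1, 0.2]))
        assert len(train) == 2 and test == []

    def test_ties_break_by_sequence(self):
        a = PeptideRecord("AAW", activity=1.0)
        b = PeptideRecord("AAC", activity=1.0)
        c = PeptideRecord("AAD", activity=0.5)
        _, test = split_train_test([a, b, c])
        assert test == [b]  # AAC sorts before AAW at equal activity

    def test_duplicate_sequences_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_train_test([PeptideRecord("AAA", activity=1.0)] * 3)


class TestMlr:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        Z = random_design(30, 2, rng)
        ys = 0.5 * Z["x1"].to_numpy() - 0.25 * Z["x2"].to_numpy()
        model = fit_mlr(Z, ys, scaling_for(ys))
        assert np.allclose(model.coefficients, [0.5, -0.25], atol=1e-12)

    def test_single_variable_coefficient_is_pearson_r(self):
        rng = np.random.default_rng(1)
        Z = random_design(40, 1, rng)
        y = 0.8 * Z["x1"].to_numpy() + rng.normal(0, 0.5, 40)
        ys = (y - y.mean()) / y.std(ddof=1)
        model = fit_mlr(Z, ys, scaling_for(y))
        r = np.corrcoef(Z["x1"], ys)[0, 1]
        # with sd conventions matched (ddof=1 both sides) beta == r exactly
        assert model.coefficients[0] == pytest.approx(r, rel=1e-9)

    def test_coefficients_within_3_se_of_truth(self):
        rng = np.random.default_rng(42)
        Z = random_design(60, 7, rng)
        beta = np.array([0.5, -0.3, 0.0, 0.2, 0.0, -0.4, 0.1])
        y = Z.to_numpy() @ beta + rng.normal(0, 0.1, 60)
        model = fit_mlr(Z, y, scaling_for(y))
        X = Z.to_numpy()
        resid = y - X @ model.coefficients
        sigma2 = resid @ resid / (60 - 7 - 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert np.all(np.abs(model.coefficients - beta) < 3 * se)

    def test_singular_design_names_collinear_variables(self):
        rng = np.random.default_rng(2)
        Z = random_design(20, 2, rng)
        Z["dup"] = Z["x1"]
        with pytest.raises(ValueError, match="collinear.*(x1|dup)"):
            fit_mlr(Z, rng.normal(size=20), scaling_for(np.arange(20.0)))


class TestPls:
    def test_full_components_equal_mlr(self):
        rng = np.random.default_rng(3)
        Z = random_design(30, 4, rng)
        y = Z.to_numpy() @ np.array([1.0, -0.5, 0.3, 0.2]) + rng.normal(0, 0.2, 30)
        ys = (y - y.mean()) / y.std(ddof=1)
        mlr = fit_mlr(Z, ys, scaling_for(y))
        pls = fit_pls(Z, ys, scaling_for(y), n_components=4)
        assert np.allclose(pls.coefficients, mlr.coefficients, atol=1e-8)

    def test_rank_one_design_predictions_independent_of_components(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=25)
        t = (t - t.mean()) / t.std(ddof=1)
        Z = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        y = t + rng.normal(0, 0.1, 25)
        ys = (y - y.mean()) / y.std(ddof=1)
        p1 = fit_pls(Z, ys, scaling_for(y), n_components=1)
        p2 = fit_pls(Z, ys, scaling_for(y), n_components=2)
        assert np.allclose(p1.predict_scaled(Z), p2.predict_scaled(Z), atol=1e-8)

    def test_matches_independent_nipals_oracle(self):
        rng = np.random.default_rng(5)
        Z = random_design(40, 6, rng)
        y = Z.to_numpy() @ rng.normal(size=6) + rng.normal(0, 0.3, 40)
        ys = (y - y.mean()) / y.std(ddof=1)
        model = fit_pls(Z, ys, scaling_for(y), n_components=3)
        beta = nipals_pls1(Z.to_numpy(), ys, 3)
        assert np.allclose(Z.to_numpy() @ beta, model.predict_scaled(Z), atol=1e-8)

    def test_component_count_bounds(self):
        rng = np.random.default_rng(6)
        Z = random_design(20, 3, rng)
        with pytest.raises(ValueError):
            fit_pls(Z, rng.normal(size=20), scaling_for(np.arange(20.0)), n_components=4)


class TestSvrRf:
    def test_rf_fits_monotone_signal(self):
        rng = np.random.default_rng(7)
        Z = random_design(200, 1, rng)
        ys = Z["x1"].to_numpy()
        model = fit_rf(Z, ys, scaling_for(ys * 2), seed=0)
        assert r2_pearson(ys, model.predict_scaled(Z)) > 0.95

    def test_svr_training_points_within_epsilon_tube(self):
        rng = np.random.default_rng(8)
        Z = random_design(50, 2, rng)
        ys = Z.to_numpy() @ np.array([0.7, -0.4])
        model = fit_svr(
            Z, ys, scaling_for(ys), seed=0,
            param_grid={"C": [100.0], "gamma": [0.1], "epsilon": [0.01]},
        )
        resid = np.abs(model.predict_scaled(Z) - ys)
        # epsilon-insensitive loss: in-tube points carry no penalty; allow a
        # small numerical margin on top of epsilon
        assert np.quantile(resid, 0.9) <= 0.011 + 0.05

    @pytest.mark.parametrize("fitter", [fit_svr, fit_rf])
    def test_same_seed_same_predictions(self, fitter):
        rng = np.random.default_rng(9)
        Z = random_design(40, 3, rng)
        ys = Z["x1"].to_numpy() + rng.normal(0, 0.2, 40)
        a = fitter(Z, ys, scaling_for(ys), seed=5)
        b = fitter(Z, ys, scaling_for(ys), seed=5)
        assert np.array_equal(a.predict_scaled(Z), b.predict_scaled(Z))

    @pytest.mark.parametrize("fitter", [fit_svr, fit_rf])
    def test_degenerate_response_rejected(self, fitter):
        rng = np.random.default_rng(10)
        Z = random_design(10, 2, rng)
        with pytest.raises(ValueError, match="zero variance"):
            fitter(Z, np.ones(10), scaling_for(np.arange(10.0)))


class TestCrossValidation:
    def _linear_setup(self, seed=11, n=25, noise=0.0):
        rng = np.random.default_rng(seed)
        Z = random_design(n, 3, rng)
        y = Z.to_numpy() @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, noise, n) + 1.0
        scaling = scaling_for(y)
        fitter = lambda Zs, ys: fit_mlr(Zs, ys, scaling)
        return Z, y, scaling, fitter

    def test_noiseless_fit_has_press_zero_q2_one(self):
        Z, y, scaling, fitter = self._linear_setup(noise=0.0)
        q2, press = loo_q2(fitter, Z, y, scaling)
        assert press == pytest.approx(0.0, abs=1e-16)
        assert q2 == pytest.approx(1.0, abs=1e-12)

    def test_press_matches_hat_matrix_shortcut(self):
        Z, y, scaling, fitter = self._linear_setup(noise=0.3)
        _, press = loo_q2(fitter, Z, y, scaling)
        X = Z.to_numpy()
        ys = scaling.scale_y(y)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        e = ys - H @ ys
        press_hat = float(((e / (1 - np.diag(H))) ** 2).sum()) * scaling.y_sd**2
        assert press == pytest.approx(press_hat, rel=1e-10)

    def test_constant_prediction_model_has_nonpositive_q2(self):
        Z, y, scaling, _ = self._linear_setup(noise=0.5)

        class Constant:
            def predict(self, Zs):
                return np.full(len(Zs), scaling.y_mean)

        fitter = lambda Zs, ys: Constant()
        q2, _ = loo_q2(fitter, Z, y, scaling)
        assert q2 <= 0.0 + 1e-9

    def test_kfold_with_k_equal_rows_reduces_to_loo(self):
        Z, y, scaling, fitter = self._linear_setup(noise=0.4)
        q2_loo, _ = loo_q2(fitter, Z, y, scaling)
        q2_k = kfold_q2(fitter, Z, y, scaling, k=len(y), shuffle=False)
        assert q2_k == pytest.approx(q2_loo, rel=1e-12)

    def test_kfold_noiseless_is_one_for_any_k(self):
        Z, y, scaling, fitter = self._linear_setup(noise=0.0)
        for k in (2, 5, 10):
            assert kfold_q2(fitter, Z, y, scaling, k, seed=1) == pytest.approx(1.0, abs=1e-10)

    def test_different_seeds_allowed_to_differ(self):
        Z, y, scaling, fitter = self._linear_setup(noise=0.6, n=30)
        a = kfold_q2(fitter, Z, y, scaling, 4, seed=1)
        b = kfold_q2(fitter, Z, y, scaling, 4, seed=2)
        assert math.isfinite(a) and math.isfinite(b)
        # determinism per seed
        assert a == kfold_q2(fitter, Z, y, scaling, 4, seed=1)


class TestSummaries:
    def test_f_formula_on_printed_benchmark(self):
        # R2 = 0.893 with 60 samples and 7 variables -> F ~ 62.0
        assert f_statistic(0.893, 60, 7) == pytest.approx(61.745, rel=0.005)

    def test_perfect_fit_gives_zero_sd_infinite_f(self):
        rng = np.random.default_rng(12)
        Z = random_design(20, 2, rng)
        y = Z.to_numpy() @ np.array([1.0, -1.0]) + 2.0
        scaling = scaling_for(y)
        model = fit_mlr(Z, scaling.scale_y(y), scaling)
        metrics = summarize(model, Z, y, k_values=(4,))
        assert metrics.sd == pytest.approx(0.0, abs=1e-10)
        assert math.isinf(metrics.f_stat) or metrics.f_stat > 1e10

    def test_metrics_are_internally_consistent(self):
        rng = np.random.default_rng(13)
        Z = random_design(40, 3, rng)
        y = Z.to_numpy() @ np.array([0.8, -0.2, 0.4]) + rng.normal(0, 0.3, 40) + 0.5
        scaling = scaling_for(y)
        model = fit_mlr(Z, scaling.scale_y(y), scaling)
        metrics = summarize(model, Z, y, k_values=(4, 6))
        # Q2 = 1 - PRESS/SS_total identity, exactly as computed
        assert metrics.q2_loo == pytest.approx(1 - metrics.press / metrics.ss_total, abs=1e-12)
        assert metrics.r2_train == pytest.approx(r2_pearson(y, model.predict(Z)), abs=1e-12)
        assert metrics.q2_loo <= 1.0 and metrics.r2_train <= 1.0

    def test_activity_rescaling_rescales_predictions(self):
        rng = np.random.default_rng(14)
        Z = random_design(30, 2, rng)
        y = Z.to_numpy() @ np.array([0.9, -0.3]) + rng.normal(0, 0.2, 30) + 1.0
        s1 = scaling_for(y)
        m1 = fit_mlr(Z, s1.scale_y(y), s1)
        s2 = scaling_for(10 * y)
        m2 = fit_mlr(Z, s2.scale_y(10 * y), s2)
        assert np.allclose(10 * m1.predict(Z), m2.predict(Z), rtol=1e-10)
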