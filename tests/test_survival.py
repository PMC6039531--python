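"""Cox engine, elastic net, CV, risk groups, log-rank, adjusted models."""

import numpy as np
import pandas as pd
import pytest

from tumorshape import (
    CohortSpec,
    cox_fit,
    coxnet_fit,
    cv_select_lambda,
    gen_survival,
    km_curve,
    logrank,
    multivariate_cox,
    risk_assign,
    univariate_screen,
)
from tumorshape.survival import partial_loglik

from conftest import grid_search_beta, partial_loglik_direct, simulate_simple_survival


class TestCoxFit:
    def test_balanced_symmetric_data_gives_zero(self):
        time = np.array([1.0, 1, 2, 2])
        event = np.ones(4, dtype=int)
        x = np.array([0.0, 1, 0, 1])
        fit = cox_fit(x, time, event)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_oracle(self, small_cox_fixtures):
        for x, time, event in small_cox_fixtures:
            for ties in ("efron", "breslow"):
                fit = cox_fit(x, time, event, ties=ties)
                oracle = grid_search_beta(x, time, event, ties=ties)
                assert abs(fit.beta[0] - oracle) < 1e-4

    def test_loglik_matches_direct_formula(self, small_cox_fixtures):
        x, time, event = small_cox_fixtures[0]
        fit = cox_fit(x, time, event)
        assert fit.loglik == pytest.approx(
            partial_loglik_direct(fit.beta[0], x, time, event), abs=1e-8
        )

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        X, time, event = simulate_simple_survival(120, 0.6, seed=0,
                                                  censor_scale=120, p=3)
        fit = cox_fit(X, time, event)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = time, event
        ll = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.beta, ll.params_.values, atol=1e-4)
        assert np.allclose(fit.se, ll.standard_errors_.values, atol=1e-4)

    def test_recovers_simulated_coefficient(self):
        """Median over 20 seeds of |beta_hat - 0.7| / 0.7 stays below 15%."""
        errors = []
        for seed in range(20):
            X, time, event = simulate_simple_survival(500, 0.7, seed=seed,
                                                      censor_scale=200)
            fit = cox_fit(X, time, event)
            errors.append(abs(fit.beta[0] - 0.7) / 0.7)
        assert np.median(errors) < 0.15

    def test_hr_and_ci_consistency(self):
        X, time, event = simulate_simple_survival(80, 0.5, seed=2)
        fit = cox_fit(X, time, event)
        assert np.allclose(fit.hr, np.exp(fit.beta))
        ci = fit.ci
        assert np.allclose(ci[:, 0], np.exp(fit.beta - 1.96 * fit.se))
        assert (fit.hr > 0).all()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(np.arange(4.0), [1, 2, 3, 4], [0, 0, 0, 0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones(5), [1, 2, 3, 4, 5], [1, 1, 1, 1, 0])

    def test_separation_is_flagged_not_raised(self):
        # covariate perfectly ordered with survival: monotone likelihood
        time = np.arange(1.0, 9.0)
        x = -time
        with pytest.warns(UserWarning, match="converge"):
            fit = cox_fit(x, time, np.ones(8, dtype=int))
        assert not fit.converged


class TestUnivariateScreen:
    def test_noise_feature_selected_at_nominal_rate(self):
        hits = 0
        reps = 100
        for seed in range(reps):
            X, time, event = simulate_simple_survival(150, 0.0, seed=seed,
                                                      censor_scale=150)
            feats = pd.DataFrame({"noise": X[:, 0]})
            _, selected = univariate_screen(feats, time, event,
                                            scales={"noise": 1.0})
            hits += bool(selected)
        assert 0.005 <= hits / reps <= 0.12

    def test_true_driver_is_selected_with_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(150, 1))
            spec = CohortSpec(n_patients=150, censor_rate=0.3,
                              seed=500 + seed, beta={"f": 0.6},
                              baseline_hazard=1e-3)
            time, event = gen_survival(x, spec)
            table, selected = univariate_screen(
                pd.DataFrame({"f": x[:, 0]}), time, event, scales={"f": 1.0})
            if selected:
                hits += 1
                assert table.loc["f", "hr"] > 1
        assert hits >= 16  # >= 80% of seeds

    def test_rescaling_changes_beta_not_p(self):
        X, time, event = simulate_simple_survival(100, 0.5, seed=5,
                                                  censor_scale=100)
        feats = pd.DataFrame({"f": X[:, 0]})
        t1, _ = univariate_screen(feats, time, event, scales={"f": 1.0})
        t2, _ = univariate_screen(feats, time, event, scales={"f": 1000.0})
        assert t2.loc["f", "beta"] == pytest.approx(
            1000 * t1.loc["f", "beta"], rel=1e-6)
        assert t2.loc["f", "p"] == pytest.approx(t1.loc["f", "p"], abs=1e-10)

    def test_constant_feature_excluded_with_warning(self):
        X, time, event = simulate_simple_survival(50, 0.5, seed=6)
        feats = pd.DataFrame({"good": X[:, 0], "flat": np.ones(50)})
        with pytest.warns(UserWarning, match="flat"):
            table, selected = univariate_screen(feats, time, event,
                                                scales={})
        assert not table.loc["flat", "selected"]


class TestCoxnet:
    def test_huge_lambda_zeroes_everything(self):
        X, time, event = simulate_simple_survival(100, 0.8, seed=1, p=4)
        model = coxnet_fit(X, time, event, lam=1e6)
        assert np.allclose(model.beta, 0.0)

    def test_lambda_zero_equals_unpenalized_breslow(self):
        X, time, event = simulate_simple_survival(150, 0.6, seed=2,
                                                  censor_scale=150, p=4)
        model = coxnet_fit(X, time, event, lam=0.0)
        fit = cox_fit(X, time, event, ties="breslow")
        assert np.max(np.abs(model.beta - fit.beta)) < 1e-4

    def test_l1_norm_non_increasing_along_path(self):
        X, time, event = simulate_simple_survival(150, 0.7, seed=3,
                                                  censor_scale=150, p=5)
        model = coxnet_fit(X, time, event, lam=None)
        norms = np.abs(model.path_coefs).sum(axis=1)
        assert np.all(np.diff(norms) >= -1e-8)  # lambda decreases along path

    def test_matches_sksurv_at_moderate_lambda(self):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        X, time, event = simulate_simple_survival(200, 0.6, seed=4,
                                                  censor_scale=150, p=4)
        model = coxnet_fit(X, time, event, lam=None)
        mu, sd = X.mean(0), X.std(0)
        idx = len(model.path_lambdas) // 3
        lam = float(model.path_lambdas[idx])
        ref = CoxnetSurvivalAnalysis(l1_ratio=0.5, alphas=[lam], tol=1e-12,
                                     max_iter=10**6)
        ref.fit((X - mu) / sd, Surv.from_arrays(event.astype(bool), time))
        assert np.allclose(model.path_coefs[idx], ref.coef_[:, -1] / sd,
                           atol=1e-5)

    def test_ridge_shrinks_without_zeroing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 3))
        t_event = rng.exponential(1 / (0.01 * np.exp(X @ [0.8, 0.0, 0.0])))
        t_cens = rng.exponential(150, 150)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        fit = cox_fit(X, time, event, ties="breslow")
        lam = 0.1
        ridge = coxnet_fit(X, time, event, lam=lam, alpha_mix=0.0)
        lasso = coxnet_fit(X, time, event, lam=lam, alpha_mix=1.0)
        assert np.abs(ridge.beta).sum() < np.abs(fit.beta).sum()
        assert (ridge.beta != 0).all()   # l2 shrinks but never zeroes
        assert (lasso.beta == 0).any()   # l1 produces exact zeros


class TestCVSelectLambda:
    def test_deterministic_in_seed(self):
        X, time, event = simulate_simple_survival(120, 0.7, seed=6,
                                                  censor_scale=150, p=5)
        m1 = cv_select_lambda(X, time, event, k=5, seed=3)
        m2 = cv_select_lambda(X, time, event, k=5, seed=3)
        assert m1.lam == m2.lam and np.array_equal(m1.beta, m2.beta)

    def test_pure_noise_prefers_heavy_penalty(self):
        """With no signal, CV should park lambda near the top of the path
        (an all-null or nearly-null model) in most seeds."""
        hits = 0
        for seed in range(10):
            X, time, event = simulate_simple_survival(100, 0.0, seed=seed,
                                                      censor_scale=150, p=5)
            model = cv_select_lambda(X, time, event, k=5, seed=seed)
            path = np.asarray(model.extras["cv_lambdas"])
            rank = int(np.argmin(np.abs(path - model.lam)))
            hits += (model.beta == 0).all() or rank < 20
        assert hits >= 8

    def test_strong_two_feature_signal_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 6))
            spec = CohortSpec(n_patients=300, censor_rate=0.3,
                              seed=700 + seed, baseline_hazard=1e-3,
                              beta={"a": 0.8, "b": -0.8, "c": 0, "d": 0,
                                    "e": 0, "f": 0})
            time, event = gen_survival(X, spec)
            model = cv_select_lambda(X, time, event, k=10, seed=seed)
            hits += model.beta[0] != 0 and model.beta[1] != 0
        assert hits >= 8

    def test_more_folds_than_patients_rejected(self):
        X, time, event = simulate_simple_survival(5, 0.5, seed=7)
        with pytest.raises(ValueError, match="folds"):
            cv_select_lambda(X, time, event, k=10)


class TestRiskAssign:
    @staticmethod
    def _model(beta):
        from tumorshape import CoxnetModel

        beta = np.asarray(beta, float)
        p = beta.size
        return CoxnetModel(feature_names=[f"x{i}" for i in range(p)],
                           beta=beta, lam=0.1, alpha_mix=0.5,
                           path_lambdas=np.array([0.1]),
                           path_coefs=beta[None, :],
                           center=np.zeros(p), scale=np.ones(p))

    def test_median_split_with_strict_high(self):
        model = self._model([1.0])
        assign = risk_assign(np.array([[1.0], [2], [3], [4]]), model)
        assert assign.groups.tolist() == ["low", "low", "high", "high"]

    def test_scores_at_median_go_low(self):
        model = self._model([1.0])
        assign = risk_assign(np.array([[1.0], [2], [2], [3]]), model)
        assert assign.groups.tolist() == ["low", "low", "low", "high"]

    def test_null_model_warns_all_low(self):
        model = self._model([0.0])
        with pytest.warns(UserWarning, match="identical"):
            assign = risk_assign(np.array([[1.0], [2], [3]]), model)
        assert not assign.high.any()


class TestKaplanMeierAndLogrank:
    def test_km_two_patient_example(self):
        curve = km_curve([1.0, 2.0], [0, 1])
        # censored at 1, event at 2: survival 1 until t=2, then 0
        assert curve.loc[curve["time"] == 1.0, "survival"].iloc[0] == 1.0
        assert curve.loc[curve["time"] == 2.0, "survival"].iloc[0] == 0.0

    def test_km_no_events_is_flat(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_km_is_non_increasing(self):
        rng = np.random.default_rng(0)
        curve = km_curve(rng.exponential(10, 50),
                         rng.integers(0, 2, 50))
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_hand_computed_fixture(self):
        """Separated groups {1,2,3} vs {4,5,6}, all events: chi-square is
        the hand-derived 5.05."""
        groups = np.array(["a"] * 3 + ["b"] * 3)
        chi2, df, p = logrank(groups, [1, 2, 3, 4, 5, 6], np.ones(6, int))
        assert chi2 == pytest.approx(5.05, abs=0.01)
        assert df == 1 and p == pytest.approx(0.0246, abs=1e-3)

    def test_identical_groups_give_null_result(self):
        t = np.r_[1.0, 2, 3, 1, 2, 3]
        g = np.array(["a"] * 3 + ["b"] * 3)
        chi2, _, p = logrank(g, t, np.ones(6, int))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_leaves_chi2_unchanged(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        g = np.where(rng.random(40) < 0.5, "a", "b")
        chi2_1, _, _ = logrank(g, t, e)
        chi2_2, _, _ = logrank(np.where(g == "a", "b", "a"), t, e)
        assert chi2_1 == pytest.approx(chi2_2)

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(["a", "a"], [1, 2], [1, 1])

    def test_chi2_equals_squared_score_test(self):
        """For a binary covariate without ties, the log-rank chi-square is
        the Cox (Breslow) score test statistic."""
        rng = np.random.default_rng(2)
        n = 30
        x = rng.integers(0, 2, n).astype(float)
        t = rng.permutation(np.arange(1.0, n + 1))  # distinct times
        e = np.ones(n, dtype=int)
        chi2, _, _ = logrank(np.where(x > 0, "a", "b"), t, e)
        from tumorshape.survival import _partial_loglik_derivs, _sort_by_time

        Xs, ts, es, _ = _sort_by_time(x[:, None], t, e)
        _, g, H = _partial_loglik_derivs(Xs, ts, es, np.zeros(1), "breslow")
        score_chi2 = float(g[0] ** 2 / -H[0, 0])
        assert chi2 == pytest.approx(score_chi2, abs=1e-6)


class TestMultivariateCox:
    @staticmethod
    def _clinical(n, rng):
        return pd.DataFrame({
            "age": rng.normal(65, 8, n),
            "sex": rng.choice(["male", "female"], n),
            "smoking": rng.choice(["ever", "never"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n,
                                p=[0.55, 0.2, 0.15, 0.1]),
        })

    def test_risk_group_hr_recovered_with_noise_covariates(self):
        """True risk-group HR 2.25, clinical covariates independent of the
        hazard, n=400: estimated HR lands in [1.7, 3.0] for >= 80% of 20
        seeds, and noise covariates center on HR 1."""
        hrs = []
        noise_hrs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            high = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
            spec = CohortSpec(n_patients=n, censor_rate=0.3, seed=seed,
                              beta={"risk": np.log(2.25)},
                              baseline_hazard=5e-4)
            time, event = gen_survival(high[:, None], spec)
            fit = multivariate_cox(high.astype(int), self._clinical(n, rng),
                                   time, event)
            hrs.append(float(fit.summary.loc["risk_high_vs_low", "hr"]))
            noise_hrs.append(
                float(fit.summary.loc["smoking_ever_vs_never", "hr"]))
        assert np.mean([(1.7 <= h <= 3.0) for h in hrs]) >= 0.8
        assert 1.7 <= np.median(hrs) <= 3.0
        assert 0.8 <= np.median(noise_hrs) <= 1.25

    def test_stage_I_only_cohort_drops_stage_dummies(self):
        rng = np.random.default_rng(3)
        n = 60
        clin = self._clinical(n, rng)
        clin["stage"] = "I"
        high = rng.integers(0, 2, n)
        t = rng.exponential(100, n)
        e = np.ones(n, dtype=int)
        with pytest.warns(UserWarning, match="stage"):
            fit = multivariate_cox(high, clin, t, e)
        assert not any(name.startswith("stage") for name in fit.names)

    def test_reference_levels_define_signs(self):
        # strong stage effect: stage IV worse than I
        rng = np.random.default_rng(4)
        n = 300
        clin = self._clinical(n, rng)
        hazard = np.where(clin["stage"] == "IV", 8e-3, 1e-3)
        t = rng.exponential(1 / hazard)
        e = np.ones(n, dtype=int)
        fit = multivariate_cox(rng.integers(0, 2, n), clin, t, e)
        assert fit.summary.loc["stage_IV_vs_I", "hr"] > 2


class TestPartialLoglikHelper:
    def test_public_loglik_matches_direct_formula(self, small_cox_fixtures):
        x, time, event = small_cox_fixtures[1]
        for beta in (-0.5, 0.0, 0.8):
            assert partial_loglik(x, time, event, [beta]) == pytest.approx(
                partial_loglik_direct(beta, x, time, event), abs=1e-9)
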