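import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from escctraj.simulate import simulate_survival
from escctraj.survival import (cindex, cox_fit, decision_curve, km_estimate,
                               logrank_test, predict_survprob, ridge_cox_fit,
                               risk_score, staging_3c, td_auc,
                               train_test_split)


class TestKaplanMeier:
    def test_survival_starts_at_one(self, rng):
        t = rng.exponential(100, size=50)
        km = km_estimate(t, rng.integers(0, 2, size=50))
        assert km.survival[km.times == 0][0] == pytest.approx(1.0)

    def test_no_censoring_equals_empirical_fraction(self, rng):
        t = rng.exponential(100, size=200)
        km = km_estimate(t, np.ones(200, dtype=int))
        for q in (np.quantile(t, 0.25), np.quantile(t, 0.6)):
            emp = np.mean(t > q)
            i = np.searchsorted(km.times, q, side="right") - 1
            assert km.survival[i] == pytest.approx(emp, abs=1e-9)

    def test_product_limit_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        # S = 2/3 on [1, 3); 0 at 3
        i1 = np.searchsorted(km.times, 1.0, side="right") - 1
        i2 = np.searchsorted(km.times, 2.5, side="right") - 1
        i3 = np.searchsorted(km.times, 3.0, side="right") - 1
        assert km.survival[i1] == pytest.approx(2 / 3)
        assert km.survival[i2] == pytest.approx(2 / 3)
        assert km.survival[i3] == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = np.r_[np.arange(1, 11), np.arange(1, 11)].astype(float)
        g = np.r_[np.zeros(10), np.ones(10)]
        chi2, df, p = logrank_test(t, np.ones(20, dtype=int), g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(100, size=40)
        e = np.ones(40, dtype=int)
        g = rng.integers(0, 2, size=40)
        r1 = logrank_test(t, e, g)
        r2 = logrank_test(t, e, 1 - g)
        assert r1[0] == pytest.approx(r2[0])

    def test_six_patient_toy_matches_hand_computation(self):
        # group A times 1, 3, 5 (all events); group B times 2, 4, 6 (events)
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        e = np.ones(6, dtype=int)
        g = np.array(["A", "A", "A", "B", "B", "B"])
        # hand computation of observed - expected for group A:
        # t=1: O=1 E=3/6; t=2: O=0 E=2/5; t=3: O=1 E=2/4; t=4: O=0 E=1/3;
        # t=5: O=1 E=1/2; t=6: O=0 E=0/1
        oe = (1 - 3 / 6) + (0 - 2 / 5) + (1 - 2 / 4) + (0 - 1 / 3) + (1 - 1 / 2)
        var = sum(n1 * n2 / n ** 2 for n1, n2, n in
                  [(3, 3, 6), (2, 3, 5), (2, 2, 4), (1, 2, 3), (1, 1, 2)])
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(oe ** 2 / var, rel=1e-9)


class TestCoxFit:
    def test_null_covariate_estimate_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        t, e = simulate_survival(np.zeros(2000), 0.01, 0.2, rng)
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert abs(m.coefficients.iloc[0]) < 0.08

    def test_score_equation_satisfied_at_optimum(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        t, e = simulate_survival(0.5 * x, 0.01, 0.3, rng)
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert m.grad_norm < 1e-8

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n = 150
        X = pd.DataFrame({"a": rng.standard_normal(n),
                          "b": rng.binomial(1, 0.4, n).astype(float)})
        lp = 0.6 * X["a"].to_numpy() - 0.8 * X["b"].to_numpy()
        t, e = simulate_survival(lp, 0.01, 0.25, rng)
        t = np.ceil(t / 30)  # force many ties
        df = X.assign(T=t, E=e)
        ours = cox_fit(X, t, e)
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(ours.coefficients.to_numpy(),
                                   ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(ours.summary["se"].to_numpy(),
                                   ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"c": np.ones(10)}),
                    np.arange(1.0, 11.0), np.ones(10, dtype=int))


class TestRidgeCox:
    def _data(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"a": rng.standard_normal(n),
                          "b": rng.standard_normal(n),
                          "c": rng.standard_normal(n)})
        lp = 0.8 * X["a"].to_numpy() - 0.4 * X["b"].to_numpy()
        t, e = simulate_survival(lp, 0.01, 0.2, rng)
        return X, t, e

    def test_large_lambda_shrinks_to_zero(self):
        X, t, e = self._data()
        m = ridge_cox_fit(X, t, e, lambda_grid=[1e7], nfolds=3)
        assert np.abs(m.coefficients.to_numpy()).max() < 1e-3

    def test_lambda_zero_matches_unpenalized(self):
        X, t, e = self._data()
        m0 = cox_fit(X, t, e)
        mr = ridge_cox_fit(X, t, e, lambda_grid=[0.0], nfolds=3)
        np.testing.assert_allclose(mr.coefficients.to_numpy(),
                                   m0.coefficients.to_numpy(), atol=1e-4)

    def test_coefficient_norm_nonincreasing_in_lambda(self):
        X, t, e = self._data()
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0, 1000.0]:
            m = ridge_cox_fit(X, t, e, lambda_grid=[lam], nfolds=3)
            norms.append(np.linalg.norm(m.coefficients.to_numpy()))
        assert all(norms[i] >= norms[i + 1] - 1e-9 for i in range(4))

    def test_cv_selects_within_grid_and_records_deviance(self):
        X, t, e = self._data()
        m = ridge_cox_fit(X, t, e, lambda_grid=[0.1, 1.0, 10.0], nfolds=5,
                          seed=1)
        assert m.lam in (0.1, 1.0, 10.0)
        assert len(m.cv_deviance) == 3
        assert m.cv_deviance["mean_deviance"].notna().all()

    def test_high_dimensional_fit_recovers_signal(self):
        rng = np.random.default_rng(9)
        n, p = 100, 300
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"g{i}" for i in range(p)])
        lp = X.iloc[:, :10].sum(axis=1).to_numpy() * 0.3
        t, e = simulate_survival(lp, 0.01, 0.2, rng)
        m = ridge_cox_fit(X, t, e, lambda_grid=[10.0, 100.0], nfolds=5)
        scores = risk_score(m, X)
        assert cindex(scores.to_numpy(), t, e) > 0.7


class TestCindex:
    def test_perfect_and_constant_scores(self, rng):
        t = rng.exponential(100, size=50)
        e = np.ones(50, dtype=int)
        assert cindex(-t, t, e) == 1.0
        assert cindex(np.zeros(50), t, e) == 0.5

    def test_three_observation_toy(self):
        assert cindex([3.0, 1.0, 2.0], [1.0, 2.0, 3.0], [1, 1, 1]) \
            == pytest.approx(2 / 3)

    def test_censored_pair_permissibility_rules(self):
        # earlier-time patient with an event: pair usable (here discordant)
        assert cindex([1.0, 2.0], [1.0, 2.0], [1, 0]) == 0.0
        # earlier time censored -> no permissible pair at all
        with pytest.raises(ValueError):
            cindex([1.0, 2.0], [1.0, 2.0], [0, 1])

    @given(st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_increasing_transform(self, scale):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(40)
        t = rng.exponential(100, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        assert cindex(s, t, e) == pytest.approx(
            cindex(np.exp(scale * s), t, e))


class TestTdAuc:
    def test_equals_binary_auc_without_censoring(self, rng):
        from scipy.stats import mannwhitneyu
        n = 200
        s = rng.standard_normal(n)
        t = rng.exponential(100, size=n)
        e = np.ones(n, dtype=int)
        for th in (30.0, 80.0, 150.0):
            cases, controls = s[t <= th], s[t > th]
            u = mannwhitneyu(cases, controls).statistic
            binary = u / (len(cases) * len(controls))
            assert abs(td_auc(s, t, e, [th]).iloc[0] - binary) < 1e-10

    def test_matches_ipcw_reference_with_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        n = 300
        s = rng.standard_normal(n)
        t, e = simulate_survival(0.5 * s, 0.01, 0.3, np.random.default_rng(8))
        y = np.array(list(zip(e.astype(bool), t)),
                     dtype=[("e", bool), ("t", float)])
        ts = [40.0, 90.0, 140.0]
        ref, _ = cumulative_dynamic_auc(y, y, s, ts)
        np.testing.assert_allclose(td_auc(s, t, e, ts).to_numpy(), ref,
                                   atol=1e-10)

    def test_null_scores_near_half(self, rng):
        n = 500
        s = rng.standard_normal(n)
        t = rng.exponential(100, size=n)
        auc = td_auc(s, t, np.ones(n, dtype=int), [70.0])
        assert auc.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance_and_horizon_warning(self, rng):
        s = rng.standard_normal(60)
        t = rng.exponential(100, size=60)
        e = np.ones(60, dtype=int)
        a1 = td_auc(s, t, e, [50.0])
        a2 = td_auc(np.exp(s), t, e, [50.0])
        assert a1.iloc[0] == pytest.approx(a2.iloc[0])
        with pytest.warns(UserWarning, match="no cases or controls"):
            out = td_auc(s, t, e, [t.max() + 1])
        assert np.isnan(out.iloc[0])


class TestStaging:
    def test_separable_scores_exact_groups(self):
        scores = pd.Series(np.r_[np.zeros(10), np.full(10, 5.0),
                                 np.full(10, 10.0)],
                           index=[f"p{i}" for i in range(30)])
        st_ = staging_3c(scores, seed=0)
        assert (st_.groups.iloc[:10] == "low").all()
        assert (st_.groups.iloc[10:20] == "medium").all()
        assert (st_.groups.iloc[20:] == "high").all()

    def test_mixture_recovery_and_ascending_means(self):
        rng = np.random.default_rng(5)
        comp = rng.integers(0, 3, size=124)
        scores = pd.Series(comp * 3.0 + rng.normal(0, 0.5, size=124),
                           index=[f"p{i}" for i in range(124)])
        st_ = staging_3c(scores, seed=1)
        mapping = {"low": 0, "medium": 1, "high": 2}
        acc = np.mean([mapping[g] == c for g, c in zip(st_.groups, comp)])
        assert acc >= 0.95
        gm = st_.group_means
        assert gm["low"] < gm["medium"] < gm["high"]

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            staging_3c(pd.Series([1.0, 1.0, 2.0]), seed=0)


class TestTrainTestSplit:
    def _clin(self, n=124, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "os_time": rng.exponential(500, n), "os_event": rng.integers(0, 2, n),
            "dfs_time": rng.exponential(400, n), "dfs_event": rng.integers(0, 2, n),
            "ptnm": rng.choice(["I", "II", "III", "IV"], n),
            "t_stage": ["T2"] * n, "n_stage": ["N0"] * n,
            "sex": rng.choice(["F", "M"], n), "age": rng.normal(60, 8, n)})

    def test_default_split_sizes(self):
        train, test, rep = train_test_split(self._clin(), seed=1)
        assert len(train) == 82 and len(test) == 42

    def test_partition_property(self):
        clin = self._clin()
        train, test, _ = train_test_split(clin, seed=2)
        assert set(train) | set(test) == set(clin["patient_id"])
        assert not set(train) & set(test)

    def test_same_seed_same_split(self):
        clin = self._clin()
        t1 = train_test_split(clin, seed=3)
        t2 = train_test_split(clin, seed=3)
        assert t1[0] == t2[0] and t1[1] == t2[1]

    def test_balance_report_all_above_alpha(self):
        _, _, rep = train_test_split(self._clin(), seed=4, alpha=0.05)
        assert (rep["p"] >= 0.05).all()


class TestPredictSurvprob:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(6)
        n = 5000
        x = rng.binomial(1, 0.5, n).astype(float)
        lam, beta = 0.01, 0.6
        t, e = simulate_survival(beta * x, lam, 0.0, rng)
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        for t0 in (30.0, 70.0):
            pred = predict_survprob(m, pd.DataFrame({"x": [0.0, 1.0]}), t0)
            assert pred.iloc[0] == pytest.approx(np.exp(-lam * t0), abs=0.03)
            assert pred.iloc[1] == pytest.approx(
                np.exp(-lam * np.exp(beta) * t0), abs=0.03)

    def test_null_model_equals_baseline_for_everyone(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        t, e = simulate_survival(np.zeros(200), 0.01, 0.0, rng)
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        m.coefficients[:] = 0.0
        pred = predict_survprob(m, pd.DataFrame({"x": [-2.0, 0.0, 2.0]}), 50.0)
        assert pred.nunique() == 1

    def test_monotone_nonincreasing_in_time(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        t, e = simulate_survival(0.3 * x, 0.01, 0.0, rng)
        m = cox_fit(pd.DataFrame({"x": x}), t, e)
        probs = [predict_survprob(m, pd.DataFrame({"x": [0.5]}), tt).iloc[0]
                 for tt in (10, 50, 100, 200)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        with pytest.raises(ValueError):
            predict_survprob(m, pd.DataFrame({"x": [0.0]}), -1.0)


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_limit(self):
        pred = pd.Series([0.9, 0.8, 0.2, 0.1])
        obs = pd.Series([1.0, 1.0, 0.0, 0.0])
        dca = decision_curve(pred, obs, [0.01, 0.5])
        assert (dca["nb_none"] == 0).all()
        assert dca["nb_all"].iloc[0] == pytest.approx(
            0.5 - 0.5 * 0.01 / 0.99)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        pred = pd.Series([1.0, 1.0, 0.0, 0.0, 0.0])
        obs = pd.Series([1.0, 1.0, 0.0, 0.0, 0.0])
        dca = decision_curve(pred, obs, [0.2, 0.5, 0.8])
        np.testing.assert_allclose(dca["nb_model"], 2 / 5)

    def test_censored_patients_excluded_with_count(self):
        pred = pd.Series([0.9, 0.5, 0.1])
        obs = pd.Series([1.0, np.nan, 0.0])
        dca = decision_curve(pred, obs, [0.5])
        assert dca.attrs["n_excluded"] == 1

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            decision_curve(pd.Series([0.5]), pd.Series([1.0]), [0.0, 0.5])
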