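import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasma_surv import (
    concordance,
    fit_cox,
    kaplan_meier,
    log_rank,
    predict_lp,
    stepwise_aic,
)

from conftest import make_outcome
from oracles import (
    concordance_brute,
    cox_loglik_brute,
    km_brute,
    logrank_brute_two_group,
)


class TestFitCox:
    def test_loglik_at_zero_is_log_factorial_of_risk_sets(self):
        # 3 subjects, distinct event times: risk sets of sizes 3, 2, 1
        out = make_outcome([1.0, 2.0, 3.0], [1, 1, 1])
        m = fit_cox(np.zeros((3, 0)), out)
        assert m.loglik == pytest.approx(-np.log(6), abs=1e-12)

    def test_two_arm_exponential_recovers_log_hr(self):
        rng = np.random.default_rng(0)
        n = 1000
        arm = rng.integers(0, 2, n)
        t = rng.exponential(scale=np.exp(-np.log(2) * arm))
        out = make_outcome(t, np.ones(n))
        m = fit_cox(arm.astype(float), out)
        assert m.coef[0] == pytest.approx(np.log(2), abs=0.15)

    def test_mirrored_predictor_gives_zero_coefficient(self, rng):
        x = rng.normal(size=50)
        t = rng.exponential(size=50) + 0.01
        out = make_outcome(np.r_[t, t], np.ones(100))
        m = fit_cox(np.r_[x, -x], out)
        assert abs(m.coef[0]) < 1e-6

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        t = np.ceil(rng.exponential(scale=np.exp(-0.6 * X["a"])) * 8) / 8  # ties
        e = (rng.uniform(size=n) < 0.75).astype(int)
        out = make_outcome(t, e, ids=X.index.tolist())
        m = fit_cox(X, out)
        df = X.assign(T=t, E=e)
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(m.coef, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(m.se, ref.standard_errors_.to_numpy(), atol=1e-5)
        assert m.loglik == pytest.approx(ref.log_likelihood_, abs=1e-8)

    def test_optimum_beats_null(self, rng):
        X = rng.normal(size=(60, 2))
        t = rng.exponential(scale=np.exp(-X[:, 0]))
        out = make_outcome(t, np.ones(60))
        m = fit_cox(X, out)
        assert m.loglik >= m.loglik_null

    def test_loglik_matches_brute_force_efron(self, rng):
        for _ in range(5):
            n = 25
            X = rng.normal(size=(n, 2))
            t = np.ceil(rng.exponential(size=n) * 4) / 4
            e = (rng.uniform(size=n) < 0.7).astype(int)
            e[0] = 1
            out = make_outcome(t, e)
            m = fit_cox(X, out)
            ll = cox_loglik_brute(X, m.coef, t, e)
            assert m.loglik == pytest.approx(ll, abs=1e-8)

    def test_zero_variance_predictor_dropped_with_warning(self, rng):
        X = pd.DataFrame({"flat": np.ones(30), "x": rng.normal(size=30)})
        out = make_outcome(rng.exponential(size=30) + 0.01, np.ones(30))
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_cox(X, out)
        assert m.names == ["x"] and m.dropped == ["flat"]

    def test_separation_flagged_and_capped(self):
        # perfectly ordered predictor: monotone likelihood
        n = 12
        x = np.arange(n, dtype=float)
        out = make_outcome(n - x + 1.0, np.ones(n))
        with pytest.warns(UserWarning, match="separation|capped"):
            m = fit_cox(x, out)
        assert m.separation and abs(m.coef[0]) <= 15.0

    def test_summary_has_conventional_columns(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["u", "v"])
        out = make_outcome(rng.exponential(size=40) + 0.01, np.ones(40))
        s = fit_cox(X, out).summary()
        assert list(s.columns) == ["coef", "exp(coef)", "se(coef)", "z", "p"]
        np.testing.assert_allclose(s["exp(coef)"], np.exp(s["coef"]))


class TestPredictLp:
    def _model(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["u", "v"])
        out = make_outcome(rng.exponential(size=50) + 0.01, np.ones(50))
        return fit_cox(X, out), X

    def test_at_training_means_lp_is_zero(self, rng):
        m, X = self._model(rng)
        lp = predict_lp(m, X.mean().to_frame().T)
        assert lp.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_each_predictor(self, rng):
        m, X = self._model(rng)
        base = X.iloc[[0]].copy()
        shifted = base.copy()
        shifted["u"] += 1.0
        assert (predict_lp(m, shifted).iloc[0] - predict_lp(m, base).iloc[0]) == pytest.approx(m.coef[0])

    def test_permutation_equivariance(self, rng):
        m, X = self._model(rng)
        perm = X.iloc[::-1]
        np.testing.assert_allclose(
            predict_lp(m, perm).to_numpy(), predict_lp(m, X).to_numpy()[::-1]
        )

    def test_unknown_predictor_rejected(self, rng):
        m, X = self._model(rng)
        with pytest.raises(ValueError):
            predict_lp(m, X.rename(columns={"u": "w"}))


class TestKaplanMeier:
    def test_hand_computed_small_case(self):
        out = make_outcome([1.0, 2.0, 3.0], [1, 1, 0])
        km = kaplan_meier(out)
        curve = dict(zip(km.times, km.survival))
        assert curve[1.0] == pytest.approx(2 / 3)
        assert curve[2.0] == pytest.approx(1 / 3)
        assert curve[3.0] == pytest.approx(1 / 3)  # censoring: no drop

    def test_all_censored_flat_at_one(self):
        out = make_outcome([1.0, 2.0, 5.0], [0, 0, 0])
        km = kaplan_meier(out)
        np.testing.assert_allclose(km.survival, 1.0)

    def test_monotone_from_one(self, rng):
        t = rng.exponential(size=50) + 0.01
        e = (rng.uniform(size=50) < 0.6).astype(int)
        km = kaplan_meier(make_outcome(t, e))
        assert km.survival[0] == pytest.approx(1.0)
        assert (np.diff(km.survival) <= 1e-12).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 8), st.booleans()), min_size=2, max_size=12
        )
    )
    def test_matches_brute_force_product_limit(self, spec):
        t = np.array([a for a, _ in spec], dtype=float)
        e = np.array([int(b) for _, b in spec])
        km = kaplan_meier(make_outcome(t, e))
        bt, bS = km_brute(t, e)
        got = dict(zip(km.times, km.survival))
        for ti, Si in zip(bt, bS):
            assert got[ti] == pytest.approx(Si, abs=1e-12)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        ids = [f"s{i}" for i in range(8)]
        out = make_outcome(t, e, ids)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = log_rank(out, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(10):
            n = 20
            t = np.round(rng.exponential(size=n), 1) + 0.1
            e = (rng.uniform(size=n) < 0.7).astype(int)
            e[:2] = 1
            g = rng.integers(0, 2, n)
            g[0], g[1] = 0, 1
            ids = [f"s{i}" for i in range(n)]
            out = make_outcome(t, e, ids)
            res = log_rank(out, pd.Series(np.where(g == 0, "a", "b"), index=ids))
            assert res.statistic == pytest.approx(
                logrank_brute_two_group(t, e, g), abs=1e-8
            )
            assert res.df == 1

    def test_separated_arms_strongly_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            arm = np.repeat([0, 1], n // 2)
            t = rng.exponential(scale=np.exp(-np.log(5) * arm))
            ids = [f"s{i}" for i in range(n)]
            out = make_outcome(t, np.ones(n), ids)
            res = log_rank(out, pd.Series(arm, index=ids))
            hits += res.p_value < 0.001
        assert hits >= 19

    def test_single_group_rejected(self):
        out = make_outcome([1.0, 2.0], [1, 1], ["a", "b"])
        with pytest.raises(ValueError):
            log_rank(out, pd.Series(["g", "g"], index=["a", "b"]))


class TestConcordance:
    def test_perfect_anticoncordance_orientation(self):
        out = make_outcome([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert concordance(out, np.array([1.0, 2, 3, 4])) == pytest.approx(0.0)
        assert concordance(out, np.array([-1.0, -2, -3, -4])) == pytest.approx(1.0)

    def test_random_risk_near_half(self, rng):
        n = 2000
        t = rng.exponential(size=n) + 1e-3
        out = make_outcome(t, np.ones(n))
        c = concordance(out, rng.normal(size=n))
        assert abs(c - 0.5) < 0.05

    def test_ties_contribute_half(self):
        out = make_outcome([1.0, 2.0], [1, 1])
        assert concordance(out, np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        n = 40
        t = rng.permutation(np.arange(1.0, n + 1))
        e = (rng.uniform(size=n) < 0.7).astype(int)
        e[:3] = 1
        risk = rng.normal(size=n)
        out = make_outcome(t, e)
        assert concordance(out, risk) == pytest.approx(
            concordance_brute(t, e, risk), abs=1e-12
        )


class TestStepwiseAic:
    def test_duplicate_column_collapses_to_one(self, rng):
        x = rng.normal(size=300)
        t = rng.exponential(scale=np.exp(-x))
        ids = [f"s{i}" for i in range(300)]
        X = pd.DataFrame({"a": x, "b": x}, index=ids)
        out = make_outcome(t, np.ones(300), ids)
        m = stepwise_aic(X, out)
        assert len(m.names) == 1

    def test_noise_column_usually_dropped(self):
        drops = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            t = rng.exponential(scale=np.exp(-x))
            ids = [f"s{i}" for i in range(n)]
            X = pd.DataFrame({"signal": x, "noise": noise}, index=ids)
            m = stepwise_aic(X, make_outcome(t, np.ones(n), ids))
            drops += "noise" not in m.names and "signal" in m.names
        assert drops >= 9

    def test_strong_single_predictor_retained(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(scale=np.exp(-1.5 * x))
        ids = [f"s{i}" for i in range(n)]
        X = pd.DataFrame({"x": x}, index=ids)
        out = make_outcome(t, np.ones(n), ids)
        m = stepwise_aic(X, out)
        full = fit_cox(X, out)
        assert m.names == ["x"]
        assert full.aic < -2 * full.loglik_null  # null AIC is higher

    def test_result_aic_never_above_full_model(self, rng):
        n = 150
        X = pd.DataFrame(
            rng.normal(size=(n, 5)), columns=list("abcde"),
            index=[f"s{i}" for i in range(n)],
        )
        t = rng.exponential(scale=np.exp(-X["a"].to_numpy()))
        out = make_outcome(t, np.ones(n), X.index.tolist())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = fit_cox(X, out)
            m = stepwise_aic(X, out)
        assert m.aic <= full.aic + 1e-9
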