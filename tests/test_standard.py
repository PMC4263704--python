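import numpy as np
import pytest

from idprog.standard import (WeibullPHRegressor, fit_weibull_ph, make_m1,
                             make_m2, make_m3, surv_to_arrays,
                             survival_outcome)

from conftest import obs


@pytest.fixture(scope="module")
def mixed_obs():
    """Diagnosed+died, died-undiagnosed, transplant-censored, alive."""
    return [
        obs("diag_died", L=2.1, R=3.2, T=4.5, died=1),
        obs("died_undiag", L=1.0, T=4.0, died=1),
        obs("tx_censored", L=1.2, R=2.0, T=3.0, tx=1),
        obs("alive", L=1.0, T=6.0),
    ]


class TestDatasetConstruction:
    def test_m1(self, mixed_obs):
        m1 = {o.subject_id: o for o in make_m1(mixed_obs)}
        assert (m1["diag_died"].time, m1["diag_died"].event) == (3.2, 1)
        assert (m1["died_undiag"].time, m1["died_undiag"].event) == (4.0, 0)
        assert (m1["alive"].time, m1["alive"].event) == (6.0, 0)

    def test_m1_censor_at_last_visit_variant(self, mixed_obs):
        m1 = {o.subject_id: o
              for o in make_m1(mixed_obs, censor_dead_at="last_visit")}
        assert (m1["died_undiag"].time, m1["died_undiag"].event) == (1.0, 0)
        assert (m1["diag_died"].time, m1["diag_died"].event) == (3.2, 1)

    def test_m2(self, mixed_obs):
        m2 = {o.subject_id: o for o in make_m2(mixed_obs)}
        assert (m2["died_undiag"].time, m2["died_undiag"].event) == (4.0, 1)
        assert (m2["diag_died"].time, m2["diag_died"].event) == (3.2, 0)
        assert (m2["alive"].time, m2["alive"].event) == (6.0, 0)

    def test_m3(self, mixed_obs):
        m3 = {o.subject_id: o for o in make_m3(mixed_obs)}
        assert "died_undiag" not in m3 and "alive" not in m3
        assert (m3["diag_died"].time, m3["diag_died"].event) == (pytest.approx(1.3), 1)
        assert (m3["tx_censored"].time, m3["tx_censored"].event) == (1.0, 0)

    def test_m3_excludes_preemptive_diagnoses(self):
        o1 = obs("pre", L=1.0, R=2.5, T=2.5, tx=1)
        o1.diagnosed_by = "preemptive"
        o2 = obs("gfr", L=1.0, R=2.0, T=4.0, died=1)
        o2.diagnosed_by = "gfr"
        assert [s.subject_id for s in make_m3([o1, o2])] == ["gfr"]

    def test_m3_death_on_diagnosis_day_floored(self, caplog):
        o = obs("same_day", L=1.0, R=2.0, T=2.0, died=1)
        m3 = make_m3([o])
        assert m3[0].time == pytest.approx(1 / 730)
        assert m3[0].event == 1

    def test_event_bookkeeping(self, default_cohort):
        _, observations, _ = default_cohort
        m1, m2, m3 = (make_m1(observations), make_m2(observations),
                      make_m3(observations))
        n_diag = sum(o.observed_ill for o in observations)
        deaths = sum(o.died for o in observations)
        assert sum(s.event for s in m1) == n_diag
        assert sum(s.event for s in m2) == deaths - sum(
            o.died and o.observed_ill for o in observations)
        assert sum(s.event for s in m2) + sum(s.event for s in m3) == deaths


class TestWeibullPHFit:
    def test_exponential_closed_form_scale(self):
        data = [obs("a", T=2.0, died=1), obs("b", T=4.0, died=1),
                obs("c", T=6.0)]
        survs = make_m2(data)
        fit = fit_weibull_ph(survs, feature_names=[], fixed_shape=1.0)
        assert fit.params.scale == pytest.approx(6.0, rel=1e-7)

    def test_exponential_rate_equals_events_over_exposure(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3.0, 400)
        c = rng.uniform(0.5, 6.0, 400)
        y = survival_outcome(t <= c, np.minimum(t, c))
        est = WeibullPHRegressor(fixed_shape=1.0).fit(np.zeros((400, 0)), y)
        rate_cf = y["event"].sum() / y["time"].sum()
        assert 1.0 / est.scale_ == pytest.approx(rate_cf, rel=1e-8)

    def test_weibull_recovery_against_exponential_oracle(self):
        # shape-1 truth: free-shape MLE must sit within 3 SE of the
        # closed-form exponential MLE computed on the same draws
        rng = np.random.default_rng(7)
        n = 5000
        t = rng.exponential(5.0, n)
        time = np.minimum(t, 5.0)
        y = survival_outcome(t <= 5.0, time)
        est = WeibullPHRegressor().fit(np.zeros((n, 0)), y)
        rate_oracle = y["event"].sum() / y["time"].sum()
        se_la, se_lb = np.sqrt(np.diag(est.covariance_))[:2]
        assert abs(np.log(est.shape_)) < 3 * se_la
        assert abs(np.log(est.scale_) - np.log(1 / rate_oracle)) < 3 * se_lb
        assert est.scale_ == pytest.approx(5.0, rel=3 * se_lb)

    def test_binary_covariate_log_hr_recovery(self):
        rng = np.random.default_rng(21)
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.weibull(1.0, n) * 5.0 * np.exp(-0.5 * x)
        c = rng.uniform(1.0, 8.0, n)
        y = survival_outcome(t <= c, np.minimum(t, c))
        est = WeibullPHRegressor().fit(x.reshape(-1, 1), y)
        se = np.sqrt(est.cov_beta_[0, 0])
        assert abs(est.coef_[0] - 0.5) < 3 * se

    def test_loglik_is_local_maximum(self):
        rng = np.random.default_rng(3)
        t = rng.weibull(1.3, 300) * 4.0
        c = rng.uniform(1, 6, 300)
        y = survival_outcome(t <= c, np.minimum(t, c))
        X = np.zeros((300, 0))
        est = WeibullPHRegressor().fit(X, y)
        base = est.loglik_

        def ll(shape, scale):
            e, tt = y["event"].astype(float), y["time"]
            return float(np.sum(
                e * np.log((shape / scale) * (tt / scale) ** (shape - 1))
                - (tt / scale) ** shape))

        for ds, dc in [(1.05, 1.0), (0.95, 1.0), (1.0, 1.05), (1.0, 0.95)]:
            assert ll(est.shape_ * ds, est.scale_ * dc) <= base + 1e-9

    def test_left_truncation_exponential_closed_form(self):
        rng = np.random.default_rng(11)
        n = 2000
        entry = rng.uniform(0, 2, n)
        # exponential memorylessness: residual life after entry
        t = entry + rng.exponential(4.0, n)
        c = entry + rng.uniform(0.5, 6, n)
        y = survival_outcome(t <= c, np.minimum(t, c))
        est = WeibullPHRegressor(fixed_shape=1.0).fit(np.zeros((n, 0)), y,
                                                      entry=entry)
        rate_cf = y["event"].sum() / (y["time"] - entry).sum()
        assert 1.0 / est.scale_ == pytest.approx(rate_cf, rel=1e-7)

    def test_zero_events_rejected(self):
        y = survival_outcome([False, False], [1.0, 2.0])
        with pytest.raises(ValueError, match="event"):
            WeibullPHRegressor().fit(np.zeros((2, 0)), y)

    def test_rank_deficient_covariates_rejected(self):
        y = survival_outcome([True] * 4, [1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            WeibullPHRegressor().fit(X, y)

    def test_hr_table_ci_brackets_hr(self):
        rng = np.random.default_rng(13)
        n = 800
        X = np.column_stack([(rng.random(n) < 0.5).astype(float),
                             rng.normal(60, 10, n)])
        t = rng.weibull(1.0, n) * 6.0 * np.exp(-(0.4 * X[:, 0]))
        c = rng.uniform(1, 8, n)
        y = survival_outcome(t <= c, np.minimum(t, c))
        est = WeibullPHRegressor(feature_names=["sex", "age0"]).fit(X, y)
        tab = est.hr_table_.set_index("covariate")
        for name in ("sex", "age0"):
            row = tab.loc[name]
            assert row.ci_low < row.hr < row.ci_high
            assert 0 <= row.p <= 1
        # age HR is reported per 10-year increase
        assert tab.loc["age0"].scale == 10.0

    def test_sklearn_param_interface(self):
        est = WeibullPHRegressor(fixed_shape=1.0)
        assert est.get_params()["fixed_shape"] == 1.0
        est.set_params(fixed_shape=None, tol=1e-8)
        assert est.get_params()["fixed_shape"] is None
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)


class TestLifelinesCrossCheck:
    """Independent oracle: lifelines Weibull AFT, mapped to the PH scale.

    For a Weibull PH model with cumulative hazard (t/b)^a exp(z beta),
    the AFT representation has lambda_i = b exp(-z beta / a), rho = a,
    i.e. beta_aft = -beta_ph / a on the log-lambda scale.
    """

    def test_params_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(17)
        n = 1500
        X = np.column_stack([(rng.random(n) < 0.4).astype(float),
                             rng.normal(0, 1, n)])
        eta = 0.6 * X[:, 0] - 0.3 * X[:, 1]
        t = rng.weibull(1.4, n) * 5.0 * np.exp(-eta / 1.4)
        c = rng.uniform(1, 9, n)
        y = survival_outcome(t <= c, np.minimum(t, c))

        est = WeibullPHRegressor().fit(X, y)

        df = pd.DataFrame({"T": y["time"], "E": y["event"].astype(int),
                           "x0": X[:, 0], "x1": X[:, 1]})
        aft = lifelines.WeibullAFTFitter().fit(df, "T", "E")
        rho = float(np.exp(aft.params_[("rho_", "Intercept")]))
        lam0 = float(np.exp(aft.params_[("lambda_", "Intercept")]))
        beta_aft = np.array([aft.params_[("lambda_", "x0")],
                             aft.params_[("lambda_", "x1")]])
        assert est.shape_ == pytest.approx(rho, rel=1e-3)
        assert est.scale_ == pytest.approx(lam0, rel=1e-3)
        assert np.allclose(est.coef_, -beta_aft * rho, atol=2e-3)
        assert est.loglik_ == pytest.approx(float(aft.log_likelihood_), rel=1e-6)
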