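import numpy as np
import pytest

from idprog.illness_death import (IllnessDeathModel, IMIDParams,
                                  QuadratureConfig, fit_imid, id_outcome,
                                  loglik_contribution, observations_to_xy,
                                  total_loglik)
from idprog.simulate import RRTModel, VisitModel, default_config
from idprog.standard import SurvObservation, fit_weibull_ph
from idprog.weibull import TransitionParams

from conftest import const_rate_params, obs, simulate_binary_cohort

Q32 = QuadratureConfig(32)


def dense_grid_oracle(o, params, n_grid=100_000):
    """Brute-force trapezoid evaluation of the likelihood patterns."""
    from idprog.weibull import cum_hazard, hazard, state0_survival

    z = o.z if o.z.size else None
    p01, p02, p12 = params.p01, params.p02, params.p12
    T = o.death_obs_time

    def passage_integral(lo, hi, tau):
        u = np.linspace(lo, hi, n_grid)
        f = (state0_survival(u, p01, p02, z) * hazard(u, p01, z)
             * np.exp(cum_hazard(u, p12, z) - cum_hazard(tau, p12, z)))
        return np.trapezoid(f, u)

    if o.R is not None:
        val = passage_integral(o.L, o.R, T)
        if o.died:
            val *= hazard(T, p12, z)
        return val
    if o.died:
        direct = state0_survival(T, p01, p02, z) * hazard(T, p02, z)
        via = passage_integral(o.L, T, T) * hazard(T, p12, z)
        return direct + via
    alive = state0_survival(T, p01, p02, z)
    return alive + passage_integral(o.L, T, T)


class TestClosedForms:
    """Constant hazards 0.1/0.2/0.3 make the passage integrand constant."""

    def test_death_without_diagnosis(self, exp_params):
        o = obs(L=0.0, T=2.0, died=1)
        val = np.exp(loglik_contribution(o, exp_params, Q32))
        assert val == pytest.approx(np.exp(-0.6) * 0.26, abs=1e-10)

    def test_interval_then_death(self, exp_params):
        o = obs(L=1.0, R=2.0, T=3.0, died=1)
        val = np.exp(loglik_contribution(o, exp_params, Q32))
        assert val == pytest.approx(0.03 * np.exp(-0.9), abs=1e-10)

    def test_alive_empty_interval(self, exp_params):
        o = obs(L=1.5, T=1.5)
        q_off = QuadratureConfig(32, undiagnosed_illness_for_alive=False)
        val = np.exp(loglik_contribution(o, exp_params, q_off))
        assert val == pytest.approx(np.exp(-0.45), abs=1e-10)

    def test_alive_with_latent_onset_term(self, exp_params):
        # lam01 + lam02 = lam12 makes the integrand e^{-0.3 C} constant
        o = obs(L=1.0, T=2.0)
        val = np.exp(loglik_contribution(o, exp_params, Q32))
        expected = np.exp(-0.6) + 0.1 * np.exp(-0.6) * 1.0
        assert val == pytest.approx(expected, abs=1e-10)


class TestDenseGridOracle:
    def test_randomized_patterns_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = IMIDParams(*[
                TransitionParams(rng.uniform(0.6, 2.5), rng.uniform(2, 20),
                                 rng.normal(0, 0.4, 2))
                for _ in range(3)
            ])
            z = rng.normal(0, 1, 2)
            L = rng.uniform(0, 3)
            kind = rng.integers(3)
            if kind == 0:
                R = L + rng.uniform(0.2, 2)
                o = obs(L=L, R=R, T=R + rng.uniform(0.1, 3),
                        died=int(rng.random() < 0.6), z=z)
            elif kind == 1:
                o = obs(L=L, T=L + rng.uniform(0.2, 4), died=1, z=z)
            else:
                o = obs(L=L, T=L + rng.uniform(0.2, 4), z=z)
            got = np.exp(loglik_contribution(o, params, QuadratureConfig(64)))
            want = dense_grid_oracle(o, params)
            assert got == pytest.approx(want, rel=1e-6)


class TestTotalLoglik:
    def test_single_record_equals_contribution(self, exp_params):
        o = obs(L=0.5, R=1.5, T=2.5, died=1)
        assert total_loglik([o], exp_params, Q32) == pytest.approx(
            loglik_contribution(o, exp_params, Q32))

    def test_duplicated_record_doubles(self, exp_params):
        o = obs(L=0.5, T=3.0, died=1)
        single = total_loglik([o], exp_params, Q32)
        assert total_loglik([o, o], exp_params, Q32) == pytest.approx(2 * single)

    def test_sum_over_fixture(self, exp_params):
        rng = np.random.default_rng(1)
        fixture = []
        for i in range(20):
            L = rng.uniform(0, 2)
            if rng.random() < 0.5:
                fixture.append(obs(f"s{i}", L=L, R=L + 1, T=L + 2,
                                   died=int(rng.random() < 0.5)))
            else:
                fixture.append(obs(f"s{i}", L=L, T=L + rng.uniform(0.5, 3),
                                   died=int(rng.random() < 0.5)))
        total = total_loglik(fixture, exp_params, Q32)
        parts = sum(loglik_contribution(o, exp_params, Q32) for o in fixture)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_degenerate_interval_rejected(self, exp_params):
        o = obs(L=1.0, R=1.0, T=2.0, died=1, exact=True)
        o.illness_exact = False  # bypass the constructor guard
        with pytest.raises(ValueError, match="degenerate"):
            total_loglik([o], exp_params, Q32)

    def test_nonfinite_contribution_aborts_with_subject_id(self, exp_params,
                                                           monkeypatch):
        import idprog.illness_death as mod

        def broken(x, data):
            return np.array([0.0, -np.inf])

        monkeypatch.setattr(mod, "_loglik_per_subject", broken)
        good, bad = obs("ok", L=0.5, T=2.0, died=1), obs("fragile", L=0.5, T=3.0)
        with pytest.raises(FloatingPointError, match="fragile"):
            total_loglik([good, bad], exp_params, Q32)


class TestQuadratureBehavior:
    def test_node_doubling_converged(self, exp_params):
        rng = np.random.default_rng(9)
        fixture = []
        for i in range(30):
            L = rng.uniform(0, 2)
            if i % 3 == 0:
                fixture.append(obs(f"s{i}", L=L, R=L + rng.uniform(0.3, 1.5),
                                   T=L + 3, died=1))
            elif i % 3 == 1:
                fixture.append(obs(f"s{i}", L=L, T=L + rng.uniform(0.5, 3), died=1))
            else:
                fixture.append(obs(f"s{i}", L=L, T=L + rng.uniform(0.5, 3)))
        params = IMIDParams(TransitionParams(1.4, 8.0),
                            TransitionParams(0.9, 15.0),
                            TransitionParams(1.2, 4.0))
        a = total_loglik(fixture, params, QuadratureConfig(32))
        b = total_loglik(fixture, params, QuadratureConfig(64))
        assert abs(a - b) < 1e-8

    def test_widening_interval_increases_passage_probability(self, exp_params):
        vals = []
        for R in (1.5, 2.0, 3.0):
            o = obs(L=1.0, R=R, T=3.5, died=0)
            vals.append(loglik_contribution(o, exp_params, Q32))
        assert vals[0] < vals[1] < vals[2]

    def test_n_nodes_bounds(self):
        with pytest.raises(ValueError):
            QuadratureConfig(1)
        with pytest.raises(ValueError):
            QuadratureConfig(1000)


class TestProbabilityCoherence:
    def test_death_patterns_integrate_to_one(self, exp_params):
        """With no visits after t=0 every subject eventually contributes
        pattern (ii); its density over death time must integrate to 1."""
        from scipy.integrate import quad

        def dens(T):
            return np.exp(loglik_contribution(obs(L=0.0, T=T, died=1),
                                              exp_params, QuadratureConfig(64)))

        val, err = quad(dens, 1e-9, 200, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_m1_limit_equivalence(self):
        """With exactly observed onsets, no direct death (huge 0->2 scale)
        and death ignored, the illness-death likelihood reduces to the plain
        Weibull likelihood of the time-to-onset model."""
        params = IMIDParams(TransitionParams(1.3, 6.0),
                            TransitionParams(1.0, 1e8),
                            TransitionParams(1.0, 1e8))
        rng = np.random.default_rng(4)
        t_onset = rng.weibull(1.3, 40) * 6.0
        cens = rng.uniform(1, 8, 40)
        observations = []
        for i, (t, c) in enumerate(zip(t_onset, cens)):
            if t <= c:
                observations.append(obs(f"s{i}", L=t, R=t, T=t, exact=True))
            else:
                observations.append(obs(f"s{i}", L=c, T=c))
        got = total_loglik(observations, params,
                           QuadratureConfig(32, undiagnosed_illness_for_alive=False))
        from idprog.weibull import cum_hazard, hazard
        p01 = params.p01
        want = sum(
            np.log(hazard(t, p01)) - cum_hazard(t, p01) if t <= c
            else -cum_hazard(c, p01)
            for t, c in zip(t_onset, cens))
        # the 0->2 and 1->2 cumulative hazards at scale 1e8 are O(1e-8)
        assert got == pytest.approx(want, abs=1e-5)


class TestFitIMID:
    def test_exponential_recovery_within_3se(self):
        # rates 0.10 / 0.05 / 0.25, annual visits, admin end 10y
        params = const_rate_params(0.10, 0.05, 0.25)
        cfg = default_config(
            n=3000, params=params, reference=(0.0, 0.0, 0.0, 0.0),
            admin_lo=1.0, admin_hi=10.0,
            visits=VisitModel(mean_gap=1.0, gap_jitter=0.2, dropout=0.10),
            rrt=RRTModel(p_preemptive=0.0, p_dialysis=0.0, p_transplant=0.0),
            seed=23)
        from idprog.cohort import derive_id_observation
        from idprog.simulate import simulate_cohort
        from dataclasses import replace

        records, _ = simulate_cohort(cfg)
        observations = [replace(derive_id_observation(r), z=np.zeros(0))
                        for r in records]
        fit = fit_imid(observations, feature_names=[])
        assert fit.converged
        se = np.sqrt(np.diag(fit.covariance))
        truth = np.log([1.0, 10.0, 1.0, 20.0, 1.0, 4.0])
        got = np.concatenate([
            [np.log(tp.shape), np.log(tp.scale)] for tp in fit.params])
        assert np.all(np.abs(got - truth) < 3 * se)

    def test_covariate_on_progression_only(self, recovery_scenario):
        """Binary covariate with log-HR 0.588 on 0->1 only: recovered there,
        and the 0->2 coefficient CI covers zero."""
        from dataclasses import replace as dreplace

        params = IMIDParams(
            TransitionParams(1.2, 8.0, np.array([0.588])),
            TransitionParams(1.1, 18.0, np.array([0.0])),
            TransitionParams(1.0, 5.0, np.array([0.0])))
        cfg = dreplace(recovery_scenario, n=2000, params=params, seed=31)
        observations = simulate_binary_cohort(cfg)
        fit = fit_imid(observations, feature_names=["x"])
        tab01 = fit.hr_tables["01"].iloc[0]
        tab02 = fit.hr_tables["02"].iloc[0]
        se01 = tab01.se
        assert abs(tab01.log_hr - 0.588) < 3 * se01
        assert tab02.ci_low < 1.0 < tab02.ci_high

    def test_sklearn_interface_and_outcome_packing(self, exp_params):
        est = IllnessDeathModel(n_nodes=16)
        assert est.get_params()["n_nodes"] == 16
        est.set_params(n_nodes=32)
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
        o = obs(L=0.5, R=1.5, T=2.5, died=1, z=[1.0])
        X, y = observations_to_xy([o])
        assert y["L"][0] == 0.5 and y["died"][0]
        assert X.shape == (1, 1)
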