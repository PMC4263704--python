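import numpy as np
import pytest

from idprog import (IDObservation, IMIDParams, TransitionParams,
                    default_config, simulate_cohort)
from idprog.cohort import derive_id_observation
from idprog.simulate import RRTModel, VisitModel


def const_rate_params(l01=0.1, l02=0.2, l12=0.3):
    """Constant-hazard (exponential) illness-death parameters, no covariates."""
    return IMIDParams(
        TransitionParams(1.0, 1.0 / l01),
        TransitionParams(1.0, 1.0 / l02),
        TransitionParams(1.0, 1.0 / l12),
    )


def obs(sid="s", L=0.0, R=None, T=1.0, died=0, tx=0, z=(), exact=False):
    """Terse IDObservation builder for tests."""
    return IDObservation(
        subject_id=sid, L=L, R=R, death_obs_time=T, died=died,
        death_censored_at_transplant=tx, followup_end=T,
        z=np.asarray(z, dtype=float), illness_exact=exact,
    )


@pytest.fixture(scope="session")
def exp_params():
    return const_rate_params()


@pytest.fixture(scope="session")
def recovery_scenario():
    """Visits-only scenario (non-informative observation) with one binary
    covariate acting on all three transitions; used by recovery tests."""
    params = IMIDParams(
        TransitionParams(1.2, 8.0, np.array([0.4])),
        TransitionParams(1.1, 18.0, np.array([0.3])),
        TransitionParams(1.0, 5.0, np.array([0.2])),
    )
    return default_config(
        n=1500, params=params, reference=(0.0,),
        admin_lo=1.0, admin_hi=10.0,
        visits=VisitModel(mean_gap=1.0, gap_jitter=0.2, dropout=0.10),
        rrt=RRTModel(p_preemptive=0.0, p_dialysis=0.0, p_transplant=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort and its derived observations."""
    records, truth = simulate_cohort(default_config(seed=3))
    observations = [derive_id_observation(r) for r in records]
    return records, observations, truth


def simulate_binary_cohort(cfg, seed=None):
    """Simulate under a one-covariate scenario, replacing the standard
    4-covariate draw with a Bernoulli(0.5) covariate.

    The stock generator always draws the four CKD covariates; scenarios with
    a single synthetic covariate re-map the latent draws through the
    configured params directly.
    """
    from idprog.simulate import (_subject_rng, apply_observation_scheme,
                                 simulate_latent_path)

    seed = cfg.seed if seed is None else int(seed)
    records, zs = [], []
    for i in range(cfg.n):
        rng = _subject_rng(seed, i)
        z = np.array([float(rng.random() < 0.5)])
        path = simulate_latent_path(cfg.params, z, rng, reference=cfg.reference)
        rec = apply_observation_scheme(path, np.array([z[0], 0.0, 0.0, 40.0]),
                                       cfg, rng, subject_id=f"s{i:05d}")
        records.append(rec)
        zs.append(z)
    obs_list = []
    for rec, z in zip(records, zs):
        o = derive_id_observation(rec)
        o.z = np.asarray(z, dtype=float)
        obs_list.append(o)
    return obs_list
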