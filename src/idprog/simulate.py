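"""Synthetic cohorts with the observation process of a CKD referral study.

The generator draws latent three-state Weibull paths (healthy -> stage ->
death, plus direct death) with covariate effects, then overlays the
observation scheme the analysis has to cope with: GFR measured only at
intermittent visits with per-visit dropout, death ascertained exactly
(registry linkage), renal replacement therapy (dialysis / preemptive
transplantation) acting as an alternative diagnosis route, nonpreemptive
transplantation censoring death, and staggered administrative end of
follow-up.

GFR values at visits are generated only to encode detection (above/below
the stage threshold with exact fidelity to the latent onset time); the
linear-decline-with-noise proxy is for realism, not a longitudinal
trajectory model.

Default parameters emulate a nephrology referral cohort of ~1500 subjects
with stages 1-4 at inclusion, roughly annual visits, ~19% observed stage
diagnoses and ~7% deaths without prior diagnosis over follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import COVARIATES, CohortRecord, IDObservation, derive_id_observation
from .illness_death import IMIDParams
from .weibull import TransitionParams

__all__ = [
    "CovariateModel",
    "VisitModel",
    "RRTModel",
    "SimulationConfig",
    "LatentPath",
    "default_true_params",
    "default_config",
    "simulate_latent_path",
    "latent_exit_times",
    "apply_observation_scheme",
    "simulate_cohort",
    "simulate_exact_observations",
    "write_cohort",
    "config_from_yaml",
]


@dataclass(frozen=True)
class CovariateModel:
    """Marginal baseline-covariate distributions (no correlations modeled)."""

    sex_p_female: float = 0.315
    age_mean: float = 58.9
    age_sd: float = 15.1
    mgfr_mean: float = 43.1
    mgfr_sd: float = 18.4
    mgfr_floor: float = 15.0
    log_pcr_mean: float = 3.31  # log(27.4 mg/mmol)
    log_pcr_sd: float = 1.5


@dataclass(frozen=True)
class VisitModel:
    """Intermittent visit schedule: roughly annual with jitter and dropout."""

    mean_gap: float = 1.05  # years between scheduled GFR measures
    gap_jitter: float = 0.3  # sd of the gap (years), truncated at 0.1
    dropout: float = 0.22  # probability of leaving the visit schedule per visit


@dataclass(frozen=True)
class RRTModel:
    """Renal replacement therapy sub-model, conditional on stage onset."""

    p_preemptive: float = 0.05  # preemptive transplant as the diagnosis route
    p_dialysis: float = 0.45  # dialysis started soon after (latent) onset
    dialysis_delay_max: float = 0.8  # uniform delay onset -> dialysis (years)
    p_transplant: float = 0.30  # nonpreemptive transplant after dialysis
    transplant_delay_mean: float = 2.0  # exponential delay dialysis -> transplant


def default_true_params() -> IMIDParams:
    """Default data-generating transition parameters.

    Covariate order (sex female, age in years, log PCR, mGFR); effects act
    relative to the reference profile of :func:`default_config` so the
    baseline scales are in years for a typical referred man of 60 with
    mGFR 43 and PCR ~27.  Effect sizes follow the pattern seen in CKD
    referral cohorts: proteinuria and low mGFR drive progression, age
    drives death on both death transitions.
    """
    return IMIDParams(
        p01=TransitionParams(1.3, 14.0, np.array([-0.083, 0.003, 0.605, -0.1079])),
        p02=TransitionParams(1.1, 78.0, np.array([-0.400, 0.0784, 0.095, -0.0094])),
        p12=TransitionParams(1.0, 13.0, np.array([-0.342, 0.0593, 0.148, -0.003])),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario definition: truth, covariates, observation process, seed."""

    n: int = 1519
    params: IMIDParams = field(default_factory=default_true_params)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    visits: VisitModel = field(default_factory=VisitModel)
    rrt: RRTModel = field(default_factory=RRTModel)
    reference: tuple = (0.0, 60.0, 3.31, 43.1)  # covariate centering for effects
    admin_lo: float = 0.3  # staggered inclusion: admin censor ~ U(lo, hi) years
    admin_hi: float = 9.3
    seed: int = 20140

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.admin_hi > self.admin_lo > 0:
            raise ValueError("need admin_hi > admin_lo > 0")
        for prob in (self.covariates.sex_p_female, self.visits.dropout,
                     self.rrt.p_preemptive, self.rrt.p_dialysis,
                     self.rrt.p_transplant):
            if not 0 <= prob <= 1:
                raise ValueError(f"probability {prob} outside [0, 1]")


def default_config(**overrides) -> SimulationConfig:
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


@dataclass(frozen=True)
class LatentPath:
    """Latent event times of one subject (years since inclusion).

    ``t01`` is the stage-onset time (None if the subject would die first),
    ``t_death`` the death time; ``route`` is '0->2' or '0->1->2'.
    """

    t01: Optional[float]
    t_death: float
    route: str


def _effective_scale(tp: TransitionParams, z_centered: np.ndarray) -> float:
    """Scale absorbing the covariate effect: L(t|z) = (t / b_z)^a."""
    eta = float(tp.beta @ z_centered) if tp.beta.size else 0.0
    return tp.scale * np.exp(-eta / tp.shape)


def simulate_latent_path(
    params: IMIDParams, z, rng: np.random.Generator,
    reference: Sequence[float] | None = None,
) -> LatentPath:
    """Draw one latent path by inverse transform of the cumulative hazards.

    Competing exit from state 0: independent cause-specific latent times,
    the earlier wins.  Given onset at u, the death time solves
    ``L12(t) - L12(u) = E`` with E ~ Exp(1) (time-since-inclusion clock).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    zc = z - np.asarray(reference, dtype=float) if reference is not None else z
    b01 = _effective_scale(params.p01, zc)
    b02 = _effective_scale(params.p02, zc)
    b12 = _effective_scale(params.p12, zc)
    e1, e2, e3 = rng.exponential(size=3)
    t01 = b01 * e1 ** (1.0 / params.p01.shape)
    t02 = b02 * e2 ** (1.0 / params.p02.shape)
    if t02 <= t01:
        return LatentPath(t01=None, t_death=float(t02), route="0->2")
    # conditional 1->2 law: L12(t) = L12(u) + E
    u = t01
    a12 = params.p12.shape
    t_death = b12 * ((u / b12) ** a12 + e3) ** (1.0 / a12)
    return LatentPath(t01=float(u), t_death=float(t_death), route="0->1->2")


def latent_exit_times(params: IMIDParams, Z, rng: np.random.Generator,
                      reference: Sequence[float] | None = None):
    """Vectorized draw of the state-0 exit time and cause for many subjects.

    Returns ``(exit_time, through_illness)`` arrays; used for distributional
    checks at large n where per-subject streams are unnecessary.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Zc = Z - np.asarray(reference, dtype=float) if reference is not None else Z
    n = Z.shape[0]
    eta01 = Zc @ params.p01.beta if params.p01.beta.size else np.zeros(n)
    eta02 = Zc @ params.p02.beta if params.p02.beta.size else np.zeros(n)
    e1, e2 = rng.exponential(size=(2, n))
    t01 = params.p01.scale * (e1 * np.exp(-eta01)) ** (1.0 / params.p01.shape)
    t02 = params.p02.scale * (e2 * np.exp(-eta02)) ** (1.0 / params.p02.shape)
    return np.minimum(t01, t02), t01 < t02


def _draw_covariates(cm: CovariateModel, rng: np.random.Generator) -> np.ndarray:
    sex = float(rng.random() < cm.sex_p_female)
    age = rng.normal(cm.age_mean, cm.age_sd)
    # truncated normal above the stage threshold (eligibility: stages 1-4)
    while True:
        mgfr = rng.normal(cm.mgfr_mean, cm.mgfr_sd)
        if mgfr > cm.mgfr_floor + 0.5:
            break
    log_pcr = rng.normal(cm.log_pcr_mean, cm.log_pcr_sd)
    return np.array([sex, age, log_pcr, mgfr])


def _gfr_proxy(t, t01, mgfr0, threshold, rng) -> float:
    """Visit GFR encoding detection exactly: below threshold iff t >= onset."""
    noise = rng.normal(0.0, 2.0)
    if t01 is not None and t >= t01:
        val = threshold * (1.0 - min(0.75, 0.15 * (t - t01) + 0.03)) + noise
        return float(np.clip(val, 1.0, threshold - 0.5))
    if t01 is not None and np.isfinite(t01):
        val = threshold + (mgfr0 - threshold) * (1.0 - t / t01) + noise
    else:
        val = threshold + (mgfr0 - threshold) * np.exp(-0.03 * t) + noise
    return float(max(val, threshold + 0.1))


def apply_observation_scheme(
    path: LatentPath, z: np.ndarray, cfg: SimulationConfig,
    rng: np.random.Generator, subject_id: str = "s", threshold: float = 15.0,
) -> CohortRecord:
    """Overlay visits, RRT events and administrative censoring on a path."""
    admin = rng.uniform(cfg.admin_lo, cfg.admin_hi)
    t01 = path.t01
    death = path.t_death
    onset_in_study = t01 is not None and t01 < min(death, admin)

    # RRT sub-model, conditional on onset during potential follow-up
    preemptive = dialysis = transplant = None
    if onset_in_study:
        horizon = min(death, admin)
        u = rng.random()
        if u < cfg.rrt.p_preemptive:
            cand = t01 + rng.uniform(0.0, cfg.rrt.dialysis_delay_max)
            if cand < horizon:
                preemptive = cand
        elif u < cfg.rrt.p_preemptive + cfg.rrt.p_dialysis:
            cand = t01 + rng.uniform(0.0, cfg.rrt.dialysis_delay_max)
            if cand < horizon:
                dialysis = cand
                if rng.random() < cfg.rrt.p_transplant:
                    tx = dialysis + rng.exponential(cfg.rrt.transplant_delay_mean)
                    if tx < horizon:
                        transplant = tx

    # visit schedule: baseline measure at t=0 is implicit (mgfr0); stop at
    # death/admin, at observed diagnosis, or at dropout
    stop = min(death, admin)
    rrt_first = min(x for x in (preemptive, dialysis, np.inf) if x is not None)
    visit_times, visit_gfr = [], []
    t = 0.0
    while True:
        t = t + max(0.1, rng.normal(cfg.visits.mean_gap, cfg.visits.gap_jitter))
        if t >= stop or t >= rrt_first:
            break
        if rng.random() < cfg.visits.dropout:
            break
        g = _gfr_proxy(t, t01 if onset_in_study else None, z[3], threshold, rng)
        visit_times.append(round(t, 6))
        visit_gfr.append(round(g, 3))
        if g < threshold:  # diagnosis observed; GFR monitoring ends
            break

    # death is registry-ascertained whenever it falls inside the study window;
    # the analysis (not the generator) censors it at transplantation
    death_time = death if death <= admin else None

    return CohortRecord(
        subject_id=subject_id,
        visit_times=visit_times,
        visit_gfr=visit_gfr,
        dialysis_time=dialysis,
        preemptive_transplant_time=preemptive,
        nonpreemptive_transplant_time=transplant,
        death_time=death_time,
        admin_censor_time=round(admin, 6),
        sex=z[0], age0=z[1], log_pcr0=z[2], mgfr0=z[3],
    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # per-subject counter streams: changing n never reshuffles earlier subjects
    return np.random.default_rng([seed, 977, index])


def simulate_cohort(cfg: SimulationConfig, seed: Optional[int] = None):
    """Simulate a full cohort.

    Returns ``(records, truth)`` where ``truth`` is a DataFrame with the
    latent onset/death times and route per subject, for recovery tests.
    """
    seed = cfg.seed if seed is None else int(seed)
    records, truth_rows = [], []
    for i in range(cfg.n):
        rng = _subject_rng(seed, i)
        z = _draw_covariates(cfg.covariates, rng)
        path = simulate_latent_path(cfg.params, z, rng, reference=cfg.reference)
        rec = apply_observation_scheme(path, z, cfg, rng, subject_id=f"s{i:05d}")
        records.append(rec)
        truth_rows.append({
            "subject_id": rec.subject_id,
            "t01": np.nan if path.t01 is None else path.t01,
            "t_death": path.t_death,
            "route": path.route,
        })
    return records, pd.DataFrame(truth_rows)


def simulate_exact_observations(
    cfg: SimulationConfig, seed: Optional[int] = None
) -> list[IDObservation]:
    """Cohort with exactly observed stage-onset times (no interval censoring).

    The continuous-monitoring limit of the observation scheme: onsets are
    observed the instant they occur, death exactly, administrative censoring
    as usual.  Observations carry ``illness_exact=True`` and empty illness
    intervals elsewhere (L equals the follow-up end), so the illness-death
    likelihood factorizes into cause-specific components.
    """
    seed = cfg.seed if seed is None else int(seed)
    out = []
    for i in range(cfg.n):
        rng = _subject_rng(seed, i)
        z = _draw_covariates(cfg.covariates, rng)
        path = simulate_latent_path(cfg.params, z, rng, reference=cfg.reference)
        admin = rng.uniform(cfg.admin_lo, cfg.admin_hi)
        sid = f"s{i:05d}"
        t01, death = path.t01, path.t_death
        if t01 is not None and t01 < min(death, admin):
            died = death <= admin
            end = death if died else admin
            out.append(IDObservation(
                subject_id=sid, L=t01, R=t01, death_obs_time=end, died=int(died),
                death_censored_at_transplant=0, followup_end=end, z=z,
                diagnosed_by="gfr", illness_exact=True,
            ))
        elif death <= admin:
            out.append(IDObservation(
                subject_id=sid, L=death, R=None, death_obs_time=death, died=1,
                death_censored_at_transplant=0, followup_end=death, z=z,
            ))
        else:
            out.append(IDObservation(
                subject_id=sid, L=admin, R=None, death_obs_time=admin, died=0,
                death_censored_at_transplant=0, followup_end=admin, z=z,
            ))
    return out


def write_cohort(records: Sequence[CohortRecord], subjects_path, visits_path) -> None:
    """Deterministic CSV export (subject-level table + long visit table)."""
    subj_rows, visit_rows = [], []
    for r in records:
        subj_rows.append({
            "subject_id": r.subject_id,
            "sex": r.sex, "age0": r.age0, "log_pcr0": r.log_pcr0, "mgfr0": r.mgfr0,
            "dialysis_time": r.dialysis_time,
            "preemptive_transplant_time": r.preemptive_transplant_time,
            "nonpreemptive_transplant_time": r.nonpreemptive_transplant_time,
            "death_time": r.death_time,
            "admin_censor_time": r.admin_censor_time,
        })
        for t, g in zip(r.visit_times, r.visit_gfr):
            visit_rows.append({"subject_id": r.subject_id, "time": t, "gfr": g})
    pd.DataFrame(subj_rows).to_csv(subjects_path, index=False, float_format="%.6f")
    pd.DataFrame(visit_rows, columns=["subject_id", "time", "gfr"]).to_csv(
        visits_path, index=False, float_format="%.6f")


def table_one(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Descriptive summary in the layout of a cohort characteristics table."""
    obs = [derive_id_observation(r) for r in records]
    n = len(records)
    fup = np.array([o.followup_end for o in obs])
    nvisit = np.array([1 + len(r.visit_times) for r in records])  # incl. baseline
    diag = [o for o in obs if o.observed_ill]
    died_nodiag = [o for o in obs if o.died and not o.observed_ill]
    died_diag = [o for o in obs if o.died and o.observed_ill]
    gaps = np.array([o.death_obs_time - o.L for o in died_nodiag])
    rows = [
        ("n", n, ""),
        ("follow-up time, mean (sd) years", f"{fup.mean():.1f} ({fup.std():.1f})", ""),
        ("number of GFR measures, mean (sd)", f"{nvisit.mean():.1f} ({nvisit.std():.1f})", ""),
        ("stage diagnosis", len(diag), f"{100 * len(diag) / n:.1f}"),
        ("  by GFR measure", sum(o.diagnosed_by == "gfr" for o in diag), ""),
        ("  by dialysis", sum(o.diagnosed_by == "dialysis" for o in diag), ""),
        ("  by preemptive transplant", sum(o.diagnosed_by == "preemptive" for o in diag), ""),
        ("death", len(died_nodiag) + len(died_diag),
         f"{100 * (len(died_nodiag) + len(died_diag)) / n:.1f}"),
        ("  without stage diagnosis", len(died_nodiag), f"{100 * len(died_nodiag) / n:.1f}"),
        ("  with stage diagnosis", len(died_diag), f"{100 * len(died_diag) / n:.1f}"),
        ("gap last healthy measure to death, mean (sd) years",
         f"{gaps.mean():.1f} ({gaps.std():.1f})" if gaps.size else "-", ""),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "value", "pct"])


# ---------------------------------------------------------------------------
# YAML scenario files
# ---------------------------------------------------------------------------

def config_from_yaml(path) -> SimulationConfig:
    """Load a scenario from YAML; omitted sections keep their defaults.

    Schema::

        n: 1519
        seed: 42
        admin: {lo: 0.3, hi: 9.3}
        reference: [0.0, 60.0, 3.31, 43.1]
        params:
          p01: {shape: 1.3, scale: 14.0, beta: [-0.083, 0.003, 0.605, -0.1079]}
          p02: {...}
          p12: {...}
        covariates: {sex_p_female: 0.315, age_mean: 58.9, ...}
        visits: {mean_gap: 1.05, gap_jitter: 0.3, dropout: 0.22}
        rrt: {p_preemptive: 0.05, ...}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    for key in ("n", "seed"):
        if key in raw:
            kw[key] = raw[key]
    if "admin" in raw:
        kw["admin_lo"] = float(raw["admin"]["lo"])
        kw["admin_hi"] = float(raw["admin"]["hi"])
    if "reference" in raw:
        kw["reference"] = tuple(float(v) for v in raw["reference"])
    if "params" in raw:
        tps = {}
        for tr in ("p01", "p02", "p12"):
            d = raw["params"][tr]
            tps[tr] = TransitionParams(
                float(d["shape"]), float(d["scale"]),
                np.asarray(d.get("beta", []), dtype=float))
        kw["params"] = IMIDParams(**tps)
    for key, cls in (("covariates", CovariateModel), ("visits", VisitModel),
                     ("rrt", RRTModel)):
        if key in raw:
            kw[key] = cls(**raw[key])
    return default_config(**kw)
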