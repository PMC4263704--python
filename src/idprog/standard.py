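"""Standard right-censored Weibull proportional-hazards analyses (M1-M3).

The three classical constructions for studying progression to the disease
stage and death with intermittent visits:

* **M1** — time from inclusion to stage diagnosis, censored at death or at
  the latest news on vital status for undiagnosed subjects.
* **M2** — time from inclusion to death *before* diagnosis, censored at
  diagnosis (cause-specific competing-risks construction).
* **M3** — time from diagnosis to death before kidney transplantation,
  censored at transplantation or latest news; subjects diagnosed by
  preemptive transplantation do not contribute.

Each is fitted by maximum likelihood under a Weibull baseline hazard with
proportional covariate effects, via :class:`WeibullPHRegressor` — a
scikit-learn style estimator taking a covariate matrix ``X`` and a
structured outcome array ``y`` with fields ``event`` and ``time`` (the
scikit-survival convention).  Optional delayed entry (left truncation) is
supported through ``fit(..., entry=...)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import IDObservation, SurvObservation
from .weibull import TransitionParams

logger = logging.getLogger(__name__)

#: half a day in years; floor for degenerate zero-length follow-up times
MIN_TIME = 1.0 / 730.0

#: per-covariate multipliers used when reporting hazard ratios (age per
#: 10-year increase, mGFR per 10-unit increase), keyed by covariate name
DEFAULT_REPORT_SCALES = {"sex": 1.0, "age0": 10.0, "log_pcr0": 1.0, "mgfr0": 10.0}

SURV_DTYPE = np.dtype([("event", "?"), ("time", "<f8")])


def survival_outcome(event, time) -> np.ndarray:
    """Pack event indicators and follow-up times into a structured array."""
    event = np.asarray(event, dtype=bool)
    time = np.asarray(time, dtype=float)
    y = np.empty(event.shape, dtype=SURV_DTYPE)
    y["event"], y["time"] = event, time
    return y


# ---------------------------------------------------------------------------
# M1 / M2 / M3 dataset construction
# ---------------------------------------------------------------------------

def _floor_time(t: float, sid: str, label: str) -> float:
    if t <= 0:
        logger.warning("%s: %s follow-up time %.4g <= 0, floored to half a day",
                       sid, label, t)
        return MIN_TIME
    return t


def make_m1(
    observations: Iterable[IDObservation], censor_dead_at: str = "death"
) -> list[SurvObservation]:
    """Time to stage diagnosis, censored at death / latest news.

    ``censor_dead_at='last_visit'`` activates the alternative scheme that
    censors subjects who died undiagnosed at their last healthy visit instead
    of at death; it conditions on the future and is provided only for bias
    experiments.
    """
    if censor_dead_at not in ("death", "last_visit"):
        raise ValueError("censor_dead_at must be 'death' or 'last_visit'")
    out = []
    for o in observations:
        if o.observed_ill:
            t, d = o.R, 1
        elif o.died and censor_dead_at == "last_visit":
            t, d = o.L, 0
        else:
            t, d = o.death_obs_time if o.died else o.followup_end, 0
        out.append(SurvObservation(o.subject_id, _floor_time(t, o.subject_id, "M1"), d, o.z))
    return out


def make_m2(observations: Iterable[IDObservation]) -> list[SurvObservation]:
    """Time to death before diagnosis, censored at diagnosis / latest news."""
    out = []
    for o in observations:
        if o.observed_ill:
            t, d = o.R, 0
        elif o.died:
            t, d = o.death_obs_time, 1
        else:
            t, d = o.followup_end, 0
        out.append(SurvObservation(o.subject_id, _floor_time(t, o.subject_id, "M2"), d, o.z))
    return out


def make_m3(observations: Iterable[IDObservation]) -> list[SurvObservation]:
    """Time from diagnosis to death before transplantation.

    Only diagnosed subjects contribute; those whose diagnosis was the
    preemptive transplant itself are excluded (their post-diagnosis death
    follow-up is censored at time zero).
    """
    out = []
    for o in observations:
        if not o.observed_ill or o.diagnosed_by == "preemptive":
            continue
        t = o.death_obs_time - o.R
        out.append(
            SurvObservation(o.subject_id, _floor_time(t, o.subject_id, "M3"),
                            int(o.died), o.z)
        )
    if not out:
        raise ValueError("no diagnosed subjects available for the post-diagnosis model")
    return out


def surv_to_arrays(observations: Sequence[SurvObservation]):
    """(X, y, ids) arrays from a list of single-event observations."""
    X = np.vstack([o.z for o in observations]) if observations else np.zeros((0, 0))
    y = survival_outcome([o.event for o in observations], [o.time for o in observations])
    ids = [o.subject_id for o in observations]
    return X, y, ids


# ---------------------------------------------------------------------------
# Weibull PH maximum likelihood
# ---------------------------------------------------------------------------

def _weibull_ph_loglik_grad(x, logt, event, Z, entry_logt, fixed_log_shape):
    """Negative log-likelihood and gradient on (log a, log b, beta).

    loglik = sum d*(log h(t)) - [Lambda(t) - Lambda(entry)] with
    log h = la + (a-1) log t - a lb + eta and Lambda = exp(a(log t - lb) + eta).
    """
    if fixed_log_shape is None:
        la, lb, beta = x[0], x[1], x[2:]
    else:
        la, lb, beta = fixed_log_shape, x[0], x[1:]
    a = np.exp(la)
    eta = Z @ beta if Z.shape[1] else np.zeros(len(logt))
    lam = np.exp(a * (logt - lb) + eta)
    if entry_logt is not None:
        lam_e = np.exp(a * (entry_logt - lb) + eta)
    else:
        lam_e = np.zeros(len(logt))
    dlam = lam - lam_e
    log_h = la + (a - 1.0) * logt - a * lb + eta
    ll = float(np.sum(event * log_h) - np.sum(dlam))

    # gradient
    g_lb = -a * np.sum(event) + a * np.sum(dlam)
    if entry_logt is not None:
        # lam_e is 0 where entry_logt = -inf (entry at the time origin)
        entry_term = np.where(np.isfinite(entry_logt), lam_e * (entry_logt - lb), 0.0)
    else:
        entry_term = 0.0
    d_lam_la = a * (lam * (logt - lb) - entry_term)
    g_la = float(np.sum(event * (1.0 + a * (logt - lb))) - np.sum(d_lam_la))
    g_beta = Z.T @ (event - dlam) if Z.shape[1] else np.zeros(0)
    if fixed_log_shape is None:
        grad = np.concatenate([[g_la, g_lb], g_beta])
    else:
        grad = np.concatenate([[g_lb], g_beta])
    return -ll, -grad


def wald_hr_table(beta, cov_beta, names, report_scales=None) -> pd.DataFrame:
    """HR, 95% Wald CI and two-sided p-value per covariate.

    ``report_scales`` maps covariate names to the increment the HR is
    reported for (e.g. 10 for age per 10-year increase); defaults cover the
    package's standard covariates, 1 otherwise.
    """
    scales = dict(DEFAULT_REPORT_SCALES)
    if report_scales:
        scales.update(report_scales)
    rows = []
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None)) if cov_beta is not None else \
        np.full(len(beta), np.nan)
    for j, name in enumerate(names):
        s = scales.get(name, 1.0)
        b, sb = beta[j] * s, se[j] * s
        z = b / sb if sb > 0 else np.nan
        rows.append({
            "covariate": name,
            "scale": s,
            "log_hr": b,
            "se": sb,
            "hr": np.exp(b),
            "ci_low": np.exp(b - 1.959963984540054 * sb),
            "ci_high": np.exp(b + 1.959963984540054 * sb),
            "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
        })
    return pd.DataFrame(rows)


def _fd_hessian(fun, x, step=1e-5):
    """Central-difference Hessian of a scalar function."""
    p = len(x)
    H = np.empty((p, p))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


class WeibullPHRegressor:
    """Weibull proportional-hazards regression for right-censored data.

    Parameters
    ----------
    fixed_shape : float, optional
        Fix the Weibull shape (1.0 gives the exponential model) instead of
        estimating it.
    feature_names : sequence of str, optional
        Names used in the hazard-ratio table; defaults to ``x0, x1, ...`` or
        the DataFrame columns when ``X`` is a DataFrame.
    report_scales : dict, optional
        Covariate-name -> increment for HR reporting (see
        :func:`wald_hr_table`).
    tol, max_iter
        Optimizer convergence controls.

    Attributes
    ----------
    shape_, scale_ : float
        Fitted baseline Weibull parameters (scale for covariates at zero).
    coef_ : ndarray
        Per-unit log hazard ratios.
    params_ : TransitionParams
    covariance_ : ndarray
        Inverse observed information on (log shape, log scale, beta); only
        the estimated parameters appear.
    hr_table_ : DataFrame
    loglik_, converged_, n_used_, n_events_
    """

    def __init__(self, fixed_shape=None, feature_names=None, report_scales=None,
                 tol=1e-10, max_iter=500):
        self.fixed_shape = fixed_shape
        self.feature_names = feature_names
        self.report_scales = report_scales
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {"fixed_shape": self.fixed_shape, "feature_names": self.feature_names,
                "report_scales": self.report_scales, "tol": self.tol,
                "max_iter": self.max_iter}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, entry=None):
        """Fit by maximum likelihood.

        Parameters
        ----------
        X : array-like (n, p) or DataFrame
            Covariates (may have zero columns for a baseline-only fit).
        y : structured array with fields ``event`` (bool) and ``time`` (float)
            See :func:`survival_outcome`.
        entry : array-like, optional
            Delayed-entry (left truncation) times on the same clock as
            ``time``; subjects are conditioned on being event-free at entry.
        """
        names = self.feature_names
        if isinstance(X, pd.DataFrame):
            names = names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.size == 0:
            X = X.reshape(len(y), 0)
        event = np.asarray(y["event"], dtype=float)
        time = np.asarray(y["time"], dtype=float)
        if np.any(time <= 0):
            raise ValueError("all follow-up times must be > 0")
        if event.sum() < 1:
            raise ValueError("need at least one event to fit")
        if X.shape[1]:
            if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
                raise ValueError("covariate matrix is rank deficient")
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

        # center covariates: identical beta, better conditioned baseline
        center = X.mean(axis=0) if X.shape[1] else np.zeros(0)
        Xc = X - center
        logt = np.log(time)
        entry_logt = None
        if entry is not None:
            entry = np.asarray(entry, dtype=float)
            if np.any(entry < 0) or np.any(entry >= time):
                raise ValueError("entry times must satisfy 0 <= entry < time")
            with np.errstate(divide="ignore"):
                entry_logt = np.where(entry > 0, np.log(np.maximum(entry, 1e-300)), -np.inf)

        fixed_ls = None if self.fixed_shape is None else float(np.log(self.fixed_shape))
        # exponential-rate starting value
        lb0 = float(np.log(time.sum() / event.sum()))
        x0 = ([0.0, lb0] if fixed_ls is None else [lb0]) + [0.0] * X.shape[1]

        def nll(x):
            return _weibull_ph_loglik_grad(np.asarray(x), logt, event, Xc,
                                           entry_logt, fixed_ls)

        res = optimize.minimize(
            nll, np.asarray(x0), jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9,
                     "maxls": 60},
        )
        x = res.x
        if fixed_ls is None:
            la, lb, beta = x[0], x[1], x[2:]
        else:
            la, lb, beta = fixed_ls, x[0], x[1:]

        self.converged_ = bool(res.success)
        if not self.converged_:
            logger.warning("Weibull PH fit did not converge: %s", res.message)
        H = _fd_hessian(lambda v: nll(v)[0], x)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError("negative variance")
        except np.linalg.LinAlgError:
            warnings.warn("observed information not invertible; no standard errors")
            cov = np.full((len(x), len(x)), np.nan)

        shape = float(np.exp(la))
        # de-center: (t/b_c)^a e^{beta (z-c)} = (t/(b_c e^{beta c / a}))^a e^{beta z}
        scale_c = float(np.exp(lb))
        scale = scale_c * float(np.exp((beta @ center) / shape)) if X.shape[1] else scale_c

        self.shape_, self.scale_, self.coef_ = shape, scale, np.asarray(beta)
        self.params_ = TransitionParams(shape, scale, np.asarray(beta))
        self.covariance_ = cov
        k = 0 if fixed_ls is None else 1  # offset of beta block in x
        self.cov_beta_ = cov[2 - k:, 2 - k:]
        self.loglik_ = float(-res.fun)
        self.n_used_ = len(time)
        self.n_events_ = int(event.sum())
        self.feature_names_ = names
        self.hr_table_ = wald_hr_table(self.coef_, self.cov_beta_, names,
                                       self.report_scales)
        return self

    # -- prediction ---------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted")

    def predict_cumulative_hazard(self, X, times):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        eta = X @ self.coef_ if X.shape[1] else np.zeros(X.shape[0])
        return (times[None, :] / self.scale_) ** self.shape_ * np.exp(eta)[:, None]

    def predict_survival_function(self, X, times):
        return np.exp(-self.predict_cumulative_hazard(X, times))

    def score(self, X, y):
        """Mean log-likelihood per observation at the fitted parameters."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        logt = np.log(np.asarray(y["time"], dtype=float))
        event = np.asarray(y["event"], dtype=float)
        nll, _ = _weibull_ph_loglik_grad(
            np.concatenate([[np.log(self.shape_), np.log(self.scale_)], self.coef_]),
            logt, event, X, None, None)
        return -nll / len(event)


@dataclass
class FitResult:
    """Flat summary of a fitted single-transition model."""

    params: TransitionParams
    cov: np.ndarray
    loglik: float
    converged: bool
    n_used: int
    n_events: int
    hr_table: pd.DataFrame


def fit_weibull_ph(
    data: Sequence[SurvObservation],
    feature_names: Optional[Sequence[str]] = None,
    fixed_shape: Optional[float] = None,
    entry: Optional[Sequence[float]] = None,
    report_scales=None,
) -> FitResult:
    """Functional wrapper over :class:`WeibullPHRegressor`."""
    X, y, _ = surv_to_arrays(list(data))
    est = WeibullPHRegressor(fixed_shape=fixed_shape, feature_names=feature_names,
                             report_scales=report_scales)
    est.fit(X, y, entry=entry)
    return FitResult(est.params_, est.covariance_, est.loglik_, est.converged_,
                     est.n_used_, est.n_events_, est.hr_table_)
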