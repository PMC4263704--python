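"""The Weibull illness-death model for interval-censored data (model M4).

Three states: 0 (pre-stage, healthy), 1 (disease stage of interest, e.g.
CKD stage 5) and 2 (death), with Weibull proportional-hazards intensities
h01, h02, h12, all on the time-since-inclusion clock.  The stage is only
observed at intermittent visits, so its onset time is interval censored;
death is observed exactly.  Each subject contributes one of three
likelihood patterns (S0 is the state-0 sojourn survival
``exp(-L01 - L02)``, T the death/censoring time, C the end of follow-up):

(i)  stage observed in (L, R]::

        [ int_L^R S0(u) h01(u) exp(-(L12(T) - L12(u))) du ] * h12(T)^died

(ii) died without observed diagnosis — direct death plus possible
     unobserved passage through the stage between the last healthy visit
     L and death::

        S0(T) h02(T) + int_L^T S0(u) h01(u) exp(-(L12(T) - L12(u))) h12(T) du

(iii) alive at C::

        S0(C)  [ + int_L^C S0(u) h01(u) exp(-(L12(C) - L12(u))) du ]

     where the bracketed term (undiagnosed illness at the end of
     follow-up) is included by default and controlled by
     ``QuadratureConfig.undiagnosed_illness_for_alive``.

Integrals over the unknown onset time are evaluated by Gauss-Legendre
quadrature; all log-density arithmetic is done in log space.  When an
observation is flagged ``illness_exact`` the onset time is known exactly
and the integral collapses to the exact-onset density
``S0(u) h01(u) exp(-(L12(T)-L12(u))) h12(T)^died`` at ``u = R``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .cohort import IDObservation
from .standard import _fd_hessian, wald_hr_table
from .weibull import TransitionParams

logger = logging.getLogger(__name__)

__all__ = [
    "IMIDParams",
    "QuadratureConfig",
    "IllnessDeathModel",
    "ImidFitResult",
    "loglik_contribution",
    "total_loglik",
    "fit_imid",
    "id_outcome",
    "observations_to_xy",
]

#: exponent ceiling for cumulative hazards; keeps the objective finite at
#: extreme trial parameters during optimization
_EXP_CLIP = 250.0

TRANSITIONS = ("01", "02", "12")

ID_DTYPE = np.dtype([
    ("L", "<f8"), ("R", "<f8"), ("time", "<f8"), ("died", "?"), ("exact", "?"),
])


@dataclass(frozen=True)
class IMIDParams:
    """Parameters of the three transitions of the illness-death model."""

    p01: TransitionParams
    p02: TransitionParams
    p12: TransitionParams

    def __iter__(self):
        return iter((self.p01, self.p02, self.p12))

    def as_dict(self):
        return dict(zip(TRANSITIONS, self))


@dataclass(frozen=True)
class QuadratureConfig:
    """Numerical-integration settings for the illness-onset integrals."""

    n_nodes: int = 32
    undiagnosed_illness_for_alive: bool = True

    def __post_init__(self):
        if not 2 <= self.n_nodes <= 512:
            raise ValueError("n_nodes must lie in [2, 512]")


def id_outcome(observations: Iterable[IDObservation]) -> np.ndarray:
    """Pack IDObservations into the structured outcome array the model fits."""
    obs = list(observations)
    y = np.empty(len(obs), dtype=ID_DTYPE)
    for i, o in enumerate(obs):
        y[i] = (o.L, np.nan if o.R is None else o.R, o.death_obs_time,
                bool(o.died), bool(o.illness_exact))
    return y


def observations_to_xy(observations: Sequence[IDObservation]):
    """(X, y) pair for :meth:`IllnessDeathModel.fit` from observations."""
    X = np.vstack([o.z for o in observations]) if observations else np.zeros((0, 0))
    return X, id_outcome(observations)


# ---------------------------------------------------------------------------
# Compiled data: pattern groups with precomputed quadrature nodes
# ---------------------------------------------------------------------------

class _CompiledData:
    """Pattern-grouped arrays with quadrature nodes fixed once per fit."""

    def __init__(self, X, y, n_nodes, undiagnosed_alive, subject_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.size == 0:
            X = X.reshape(len(y), 0)
        self.n, self.p = X.shape
        self.Z = X
        self.subject_ids = subject_ids
        self.undiagnosed_alive = bool(undiagnosed_alive)

        L = np.asarray(y["L"], dtype=float)
        R = np.asarray(y["R"], dtype=float)
        T = np.asarray(y["time"], dtype=float)
        died = np.asarray(y["died"], dtype=bool)
        exact = np.asarray(y["exact"], dtype=bool)
        has_R = np.isfinite(R)

        bad = has_R & ~exact & ~(L < R)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"degenerate illness interval L == R for subject "
                f"{self._sid(i)}; exactly observed onsets must be flagged"
            )
        if np.any(T < L - 1e-12) or (np.any(has_R & (T < R - 1e-12))):
            raise ValueError("death/censoring time precedes the illness interval")

        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        self._mk = lambda lo, hi: _nodes_on(lo, hi, nodes, weights)

        self.idx_i = np.flatnonzero(has_R & ~exact)
        self.idx_ex = np.flatnonzero(has_R & exact)
        self.idx_ii = np.flatnonzero(~has_R & died)
        self.idx_iii = np.flatnonzero(~has_R & ~died)

        self.g_i = self._group(self.idx_i, L, R, T, died, upper=R)
        self.g_ii = self._group(self.idx_ii, L, R, T, died, upper=T)
        self.g_iii = self._group(self.idx_iii, L, R, T, died, upper=T)
        # exact onsets: point evaluation, no quadrature
        ix = self.idx_ex
        self.ex = dict(
            logR=_safe_log(R[ix]), logT=_safe_log(T[ix]), died=died[ix].astype(float),
            Z=self.Z[ix],
        )

    def _sid(self, i):
        return self.subject_ids[i] if self.subject_ids is not None else f"#{i}"

    def _group(self, ix, L, R, T, died, upper):
        lo, hi = L[ix], upper[ix]
        logU, logw = self._mk(lo, hi)
        return dict(
            logU=logU, logw=logw, logT=_safe_log(T[ix]),
            died=died[ix].astype(float), Z=self.Z[ix],
            width=hi - lo,
        )


def _nodes_on(lo, hi, nodes, weights):
    """Affine map of Gauss-Legendre nodes onto per-row intervals (lo, hi).

    Returns (log of node positions, log of scaled weights); rows with zero
    width get weight -inf so their integral term vanishes.
    """
    lo = np.asarray(lo, dtype=float)[:, None]
    hi = np.asarray(hi, dtype=float)[:, None]
    half = (hi - lo) / 2.0
    U = (hi + lo) / 2.0 + half * nodes[None, :]
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(half, 0.0)) + np.log(weights)[None, :]
        logU = np.log(np.maximum(U, 1e-300))
    logw = np.where(half > 0, logw, -np.inf)
    return logU, logw


def _safe_log(t):
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(np.asarray(t, dtype=float), 1e-300))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _unpack(x, p):
    """x = [la01, lb01, la02, lb02, la12, lb12, b01, b02, b12]."""
    la = x[0:6:2]
    lb = x[1:6:2]
    betas = [x[6 + k * p: 6 + (k + 1) * p] for k in range(3)]
    return la, lb, betas


def _cumhaz(logt, la, lb, eta):
    a = np.exp(la)
    expo = a * (logt - lb) + eta
    return np.exp(np.minimum(expo, _EXP_CLIP))


def _loghaz(logt, la, lb, eta):
    a = np.exp(la)
    return la - a * lb + (a - 1.0) * logt + eta


def _eta(Z, beta):
    return Z @ beta if Z.shape[1] else np.zeros(Z.shape[0])


def _log_passage_integral(g, la, lb, betas):
    """logsumexp over nodes of the passage-through-illness integrand.

    integrand(u) = S0(u) h01(u) exp(L12(u) - L12(tau)) on the row's
    interval, with tau the row's death/censoring time.
    """
    e01, e02, e12 = (_eta(g["Z"], b) for b in betas)
    logU = g["logU"]
    l01 = _cumhaz(logU, la[0], lb[0], e01[:, None])
    l02 = _cumhaz(logU, la[1], lb[1], e02[:, None])
    lh01 = _loghaz(logU, la[0], lb[0], e01[:, None])
    l12_u = _cumhaz(logU, la[2], lb[2], e12[:, None])
    l12_tau = _cumhaz(g["logT"], la[2], lb[2], e12)[:, None]
    logf = -(l01 + l02) + lh01 + (l12_u - l12_tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = logsumexp(g["logw"] + logf, axis=1)
    return np.where(np.isnan(out), -np.inf, out)


def _loglik_per_subject(x, data: _CompiledData) -> np.ndarray:
    la, lb, betas = _unpack(x, data.p)
    ll = np.empty(data.n)

    # pattern (i): illness interval observed
    g = data.g_i
    if len(data.idx_i):
        e12 = _eta(g["Z"], betas[2])
        v = _log_passage_integral(g, la, lb, betas)
        v = v + g["died"] * _loghaz(g["logT"], la[2], lb[2], e12)
        ll[data.idx_i] = v

    # exactly observed onset: density at u = R
    ex = data.ex
    if len(data.idx_ex):
        e01, e02, e12 = (_eta(ex["Z"], b) for b in betas)
        logR, logT = ex["logR"], ex["logT"]
        v = (
            -(_cumhaz(logR, la[0], lb[0], e01) + _cumhaz(logR, la[1], lb[1], e02))
            + _loghaz(logR, la[0], lb[0], e01)
            + (_cumhaz(logR, la[2], lb[2], e12) - _cumhaz(logT, la[2], lb[2], e12))
            + ex["died"] * _loghaz(logT, la[2], lb[2], e12)
        )
        ll[data.idx_ex] = v

    # pattern (ii): death without observed diagnosis
    g = data.g_ii
    if len(data.idx_ii):
        e01, e02, e12 = (_eta(g["Z"], b) for b in betas)
        logT = g["logT"]
        log_direct = -(
            _cumhaz(logT, la[0], lb[0], e01) + _cumhaz(logT, la[1], lb[1], e02)
        ) + _loghaz(logT, la[1], lb[1], e02)
        log_via = _log_passage_integral(g, la, lb, betas) + _loghaz(
            logT, la[2], lb[2], e12
        )
        ll[data.idx_ii] = np.logaddexp(log_direct, log_via)

    # pattern (iii): alive at the end of follow-up
    g = data.g_iii
    if len(data.idx_iii):
        e01, e02 = _eta(g["Z"], betas[0]), _eta(g["Z"], betas[1])
        logC = g["logT"]
        log_healthy = -(
            _cumhaz(logC, la[0], lb[0], e01) + _cumhaz(logC, la[1], lb[1], e02)
        )
        if data.undiagnosed_alive:
            log_latent = _log_passage_integral(g, la, lb, betas)
            ll[data.idx_iii] = np.logaddexp(log_healthy, log_latent)
        else:
            ll[data.idx_iii] = log_healthy

    return ll


def _pack_params(params: IMIDParams, p: int) -> np.ndarray:
    x = np.empty(6 + 3 * p)
    for k, tp in enumerate(params):
        beta = np.zeros(p) if tp.beta.size == 0 else np.asarray(tp.beta, dtype=float)
        if beta.size != p:
            raise ValueError(f"beta length {beta.size} != covariate count {p}")
        x[2 * k], x[2 * k + 1] = np.log(tp.shape), np.log(tp.scale)
        x[6 + k * p: 6 + (k + 1) * p] = beta
    return x


def loglik_contribution(
    o: IDObservation, params: IMIDParams, q: QuadratureConfig = QuadratureConfig()
) -> float:
    """Log-density of one subject's observed outcome pattern."""
    X, y = observations_to_xy([o])
    p = X.shape[1]
    data = _CompiledData(X, y, q.n_nodes, q.undiagnosed_illness_for_alive,
                         subject_ids=[o.subject_id])
    val = float(_loglik_per_subject(_pack_params(params, p), data)[0])
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite likelihood contribution for subject {o.subject_id} "
            f"at params {params}"
        )
    return val


def total_loglik(
    observations: Sequence[IDObservation],
    params: IMIDParams,
    q: QuadratureConfig = QuadratureConfig(),
) -> float:
    """Sum of log contributions; any non-finite contribution aborts loudly."""
    obs = list(observations)
    X, y = observations_to_xy(obs)
    data = _CompiledData(X, y, q.n_nodes, q.undiagnosed_illness_for_alive,
                         subject_ids=[o.subject_id for o in obs])
    ll = _loglik_per_subject(_pack_params(params, X.shape[1]), data)
    if not np.all(np.isfinite(ll)):
        i = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(
            f"non-finite likelihood contribution for subject {data._sid(i)}"
        )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ImidFitResult:
    """Fitted illness-death model summary.

    ``covariance`` is on the internal scale, ordered
    (log shape01, log scale01, log shape02, log scale02, log shape12,
    log scale12, beta01..., beta02..., beta12...), with baseline entries
    transformed back to the uncentered covariate origin.
    """

    params: IMIDParams
    covariance: Optional[np.ndarray]
    loglik: float
    converged: bool
    n_used: int
    hr_tables: dict
    feature_names: list


class IllnessDeathModel:
    """Weibull illness-death model for interval-censored data.

    scikit-learn style estimator.  ``fit`` takes the covariate matrix ``X``
    (shared across the three transitions, each with its own coefficient
    vector) and a structured outcome array ``y`` with fields ``L``, ``R``
    (NaN when the stage was never observed), ``time`` (death or censoring
    time), ``died`` and ``exact`` — see :func:`id_outcome`.

    Parameters
    ----------
    n_nodes : int
        Gauss-Legendre nodes for the onset-time integrals.
    undiagnosed_illness_for_alive : bool
        Whether subjects alive at the end of follow-up may harbor an
        undiagnosed stage after their last healthy visit.
    compute_covariance : bool
        Invert the observed information at the optimum (finite differences);
        disable for speed in pure point-estimation loops.

    Attributes
    ----------
    params_ : IMIDParams
    covariance_ : ndarray or None
    hr_tables_ : dict of transition -> DataFrame
    loglik_, converged_, n_used_
    """

    def __init__(self, n_nodes=32, undiagnosed_illness_for_alive=True,
                 feature_names=None, report_scales=None, tol=1e-10,
                 max_iter=500, compute_covariance=True):
        self.n_nodes = n_nodes
        self.undiagnosed_illness_for_alive = undiagnosed_illness_for_alive
        self.feature_names = feature_names
        self.report_scales = report_scales
        self.tol = tol
        self.max_iter = max_iter
        self.compute_covariance = compute_covariance

    def get_params(self, deep=True):
        return {
            "n_nodes": self.n_nodes,
            "undiagnosed_illness_for_alive": self.undiagnosed_illness_for_alive,
            "feature_names": self.feature_names,
            "report_scales": self.report_scales,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "compute_covariance": self.compute_covariance,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- starting values ----------------------------------------------------
    @staticmethod
    def _start(y, p):
        L, R, T = y["L"], y["R"], y["time"]
        has_R = np.isfinite(R)
        died = np.asarray(y["died"], dtype=bool)
        mid = np.where(has_R, np.where(np.isnan(R), 0.0, (L + R) / 2.0), T)
        exposure0 = float(np.sum(np.clip(mid, 1e-6, None)))
        n01 = max(int(has_R.sum()), 1)
        n02 = max(int((died & ~has_R).sum()), 1)
        scale01 = exposure0 / n01
        scale02 = exposure0 / n02
        exp12 = float(np.sum(np.clip(T[has_R] - mid[has_R], 1e-6, None))) or 1.0
        n12 = max(int((died & has_R).sum()), 1)
        scale12 = exp12 / n12
        x0 = np.zeros(6 + 3 * p)
        x0[1], x0[3], x0[5] = np.log(scale01), np.log(scale02), np.log(scale12)
        return x0

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, subject_ids=None):
        names = self.feature_names
        if isinstance(X, pd.DataFrame):
            names = names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.size == 0:
            X = X.reshape(len(y), 0)
        p = X.shape[1]
        names = list(names) if names is not None else [f"x{j}" for j in range(p)]

        has_R = np.isfinite(np.asarray(y["R"], dtype=float))
        died = np.asarray(y["died"], dtype=bool)
        if has_R.sum() == 0 or died.sum() == 0:
            warnings.warn("fitting with no observed diagnoses or no deaths; "
                          "some transitions are weakly identified")

        center = X.mean(axis=0) if p else np.zeros(0)
        data = _CompiledData(X - center, y, self.n_nodes,
                             self.undiagnosed_illness_for_alive, subject_ids)

        def nll(x):
            ll = _loglik_per_subject(x, data)
            s = float(ll.sum())
            return np.inf if np.isnan(s) else -s

        x0 = self._start(y, p)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8,
                     "maxls": 60, "maxfun": 200000},
        )
        self.converged_ = bool(res.success)
        if not self.converged_:
            logger.warning("IMID fit did not converge: %s", res.message)

        x = res.x
        la, lb, betas = _unpack(x, p)
        shapes = np.exp(la)
        # de-center the baseline scales: b_raw = b_c * exp((beta@c)/a)
        scales_raw = np.exp(lb) * np.exp(
            np.array([betas[k] @ center for k in range(3)]) / shapes
        ) if p else np.exp(lb)

        cov_raw = None
        if self.compute_covariance:
            H = _fd_hessian(nll, x)
            try:
                cov_c = np.linalg.inv(H)
                if np.any(np.diag(cov_c) < 0):
                    raise np.linalg.LinAlgError("negative variance")
                cov_raw = self._decenter_cov(cov_c, la, betas, center, p)
            except np.linalg.LinAlgError:
                warnings.warn("observed information not invertible; "
                              "standard errors unavailable")

        tps = [
            TransitionParams(float(shapes[k]), float(scales_raw[k]),
                             np.asarray(betas[k]))
            for k in range(3)
        ]
        self.params_ = IMIDParams(*tps)
        self.covariance_ = cov_raw
        self.loglik_ = float(-res.fun)
        self.n_used_ = data.n
        self.feature_names_ = names
        self.hr_tables_ = {}
        for k, tr in enumerate(TRANSITIONS):
            sl = slice(6 + k * p, 6 + (k + 1) * p)
            cov_beta = cov_raw[sl, sl] if cov_raw is not None else None
            self.hr_tables_[tr] = wald_hr_table(betas[k], cov_beta, names,
                                                self.report_scales)
        return self

    @staticmethod
    def _decenter_cov(cov_c, la, betas, center, p):
        """Delta-method transform of the covariance to uncentered baselines.

        Only the log-scale rows change: lb_raw = lb_c + (beta@c) * exp(-la).
        """
        d = cov_c.shape[0]
        J = np.eye(d)
        if p:
            for k in range(3):
                r = 2 * k + 1
                bc = float(betas[k] @ center)
                J[r, 2 * k] = -bc * np.exp(-la[k])
                J[r, 6 + k * p: 6 + (k + 1) * p] = center * np.exp(-la[k])
        return J @ cov_c @ J.T

    def predict_loglik(self, X, y):
        """Per-subject log contributions at the fitted parameters."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        data = _CompiledData(X, y, self.n_nodes,
                             self.undiagnosed_illness_for_alive, None)
        return _loglik_per_subject(_pack_params(self.params_, data.p), data)


def fit_imid(
    observations: Sequence[IDObservation],
    feature_names: Optional[Sequence[str]] = None,
    q: QuadratureConfig = QuadratureConfig(),
    report_scales=None,
    compute_covariance: bool = True,
    max_iter: int = 500,
) -> ImidFitResult:
    """Functional wrapper over :class:`IllnessDeathModel`."""
    obs = list(observations)
    X, y = observations_to_xy(obs)
    est = IllnessDeathModel(
        n_nodes=q.n_nodes,
        undiagnosed_illness_for_alive=q.undiagnosed_illness_for_alive,
        feature_names=feature_names, report_scales=report_scales,
        compute_covariance=compute_covariance, max_iter=max_iter,
    )
    est.fit(X, y, subject_ids=[o.subject_id for o in obs])
    return ImidFitResult(
        params=est.params_, covariance=est.covariance_, loglik=est.loglik_,
        converged=est.converged_, n_used=est.n_used_, hr_tables=est.hr_tables_,
        feature_names=est.feature_names_,
    )
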