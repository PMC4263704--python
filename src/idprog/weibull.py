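"""Weibull baseline hazards with proportional covariate action.

Every transition intensity in this package has the form

    h(t | z) = (a / b) * (t / b)**(a - 1) * exp(beta @ z)

with shape ``a > 0``, scale ``b > 0`` (years) and a transition-specific
log-hazard-ratio vector ``beta``.  The cumulative hazard is
``(t / b)**a * exp(beta @ z)``.  All fitters share these primitives;
optimization elsewhere works on ``(log a, log b, beta)`` so positivity is
unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionParams",
    "hazard",
    "cum_hazard",
    "state0_survival",
]


@dataclass(frozen=True)
class TransitionParams:
    """Weibull shape/scale plus regression coefficients for one transition.

    Parameters
    ----------
    shape : float
        Weibull shape, dimensionless, > 0. Shape 1 is a constant
        (exponential) hazard; > 1 increasing, < 1 decreasing.
    scale : float
        Weibull scale in years, > 0.
    beta : array-like of shape (p,)
        Per-unit log hazard ratios of the covariates.
    """

    shape: float
    scale: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be finite and > 0, got {self.shape}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be finite and > 0, got {self.scale}")
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.ndim != 1 or not np.all(np.isfinite(beta)):
            raise ValueError("beta must be a finite 1-d vector")
        object.__setattr__(self, "beta", beta)

    def linear_predictor(self, z) -> np.ndarray:
        """``beta @ z`` for a single covariate vector or an (n, p) matrix."""
        if z is None:
            return np.zeros(())
        z = np.asarray(z, dtype=float)
        if z.ndim <= 1 and z.size == 0:
            return np.zeros(())
        return z @ self.beta


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def hazard(t, p: TransitionParams, z=None):
    """Covariate-adjusted hazard at time ``t`` (per year).

    At t=0 the Weibull hazard is 0 for shape > 1, ``exp(beta@z)/scale`` for
    shape = 1, and diverges for shape < 1 (returned as ``inf``).
    """
    t = _check_time(t)
    eta = p.linear_predictor(z)
    a, b = p.shape, p.scale
    with np.errstate(divide="ignore"):
        base = (a / b) * (t / b) ** (a - 1.0)
    return base * np.exp(eta)


def cum_hazard(t, p: TransitionParams, z=None):
    """Covariate-adjusted cumulative hazard ``(t/b)**a * exp(beta@z)``."""
    t = _check_time(t)
    eta = p.linear_predictor(z)
    return (t / p.scale) ** p.shape * np.exp(eta)


def state0_survival(t, p01: TransitionParams, p02: TransitionParams, z=None):
    """Probability of still being in the initial (healthy) state at ``t``.

    Sojourn survival against both exits: ``exp(-L01(t|z) - L02(t|z))`` where
    L0j are the cause-specific cumulative hazards of illness and death.
    """
    return np.exp(-cum_hazard(t, p01, z) - cum_hazard(t, p02, z))


# ---------------------------------------------------------------------------
# Low-level log-scale primitives operating on (log shape, log scale, eta)
# arrays.  These are what the likelihood code calls in hot loops; they accept
# broadcasting arrays and never construct TransitionParams.
# ---------------------------------------------------------------------------

def log_hazard_raw(log_t, log_shape, log_scale, eta):
    """log h(t|z) given log t; log t may be -inf only when shape >= 1."""
    a = np.exp(log_shape)
    return log_shape - a * log_scale + (a - 1.0) * log_t + eta


def cum_hazard_raw(log_t, log_shape, log_scale, eta):
    """Cumulative hazard from log t: ``exp(a*(log t - log b) + eta)``."""
    a = np.exp(log_shape)
    return np.exp(a * (log_t - log_scale) + eta)
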