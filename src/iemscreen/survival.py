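"""Weibull survival mathematics and censored maximum-likelihood fitting.

The Markov model's disease-specific annual death probabilities come from a
Weibull baseline hazard with cumulative hazard H(t) = lambda * t**gamma,
survival S(t) = exp(-H(t)) and per-cycle transition probability

    tp(u) = 1 - exp(lambda * (t - u)**gamma - lambda * t**gamma)
          = 1 - S(t) / S(t - u),

the probability of dying during the cycle ending at time t conditional on
being alive at its start.  Parameters are housed on the log scale
(``log_lambda``, ``log_gamma``) because that is how the registry-based fits
report them and how their uncertainty is propagated.

Fitting maximises the right-censored Weibull log-likelihood; the exponential
(gamma = 1) special case is fit alongside and the two are compared by AIC.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from statsmodels.tools.numdiff import approx_hess

from .params import ParamDist, fixed

__all__ = [
    "WeibullParams",
    "SurvivalFit",
    "NoEventsError",
    "cumulative_hazard",
    "survival",
    "hazard",
    "cycle_death_prob",
    "annual_death_probs",
    "fit_weibull",
    "fit_exponential",
    "select_by_aic",
]


@dataclass(frozen=True)
class WeibullParams:
    """Log-scale Weibull coefficients; lambda = exp(log_lambda), gamma = exp(log_gamma).

    Each coefficient is a :class:`ParamDist` so the probabilistic analysis can
    draw it as a normal deviate on the log scale (equivalently, lognormal on
    the natural scale).
    """

    log_lambda: ParamDist
    log_gamma: ParamDist

    @classmethod
    def from_values(cls, log_lambda: float, log_gamma: float) -> "WeibullParams":
        return cls(fixed(log_lambda), fixed(log_gamma))

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda.mean))

    @property
    def gam(self) -> float:
        return float(np.exp(self.log_gamma.mean))


def _lam_gam(p: WeibullParams | tuple) -> tuple[float, float]:
    if isinstance(p, WeibullParams):
        return p.lam, p.gam
    lam, gam = p
    return float(lam), float(gam)


def cumulative_hazard(p: WeibullParams, t) -> np.ndarray | float:
    """H(t) = lambda * t**gamma; 0 at t = 0."""
    lam, gam = _lam_gam(p)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = lam * np.power(t, gam)
    return float(out) if out.ndim == 0 else out


def survival(p: WeibullParams, t) -> np.ndarray | float:
    """S(t) = exp(-H(t)); 1 at t = 0, non-increasing."""
    h = cumulative_hazard(p, t)
    return np.exp(-h) if isinstance(h, np.ndarray) else float(np.exp(-h))


def hazard(p: WeibullParams, t) -> np.ndarray | float:
    """h(t) = lambda * gamma * t**(gamma-1); increasing in t iff gamma > 1."""
    lam, gam = _lam_gam(p)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) and gam < 1:
        raise ValueError("hazard diverges at t = 0 for gamma < 1")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = lam * gam * np.power(t, gam - 1.0)
    return float(out) if out.ndim == 0 else out


def cycle_death_prob(p: WeibullParams, t, u: float = 1.0) -> np.ndarray | float:
    """tp(u) = 1 - exp(lambda*(t-u)**gamma - lambda*t**gamma) = 1 - S(t)/S(t-u).

    ``t`` is the time at the end of the cycle; ``u`` the cycle length.  The
    first cycle (t = u) uses the limit form 1 - exp(-lambda * u**gamma).
    """
    lam, gam = _lam_gam(p)
    t = np.asarray(t, dtype=float)
    if u <= 0:
        raise ValueError("cycle length must be positive")
    if np.any(t < u):
        raise ValueError("cycle end time must be >= cycle length")
    out = -np.expm1(lam * np.power(t - u, gam) - lam * np.power(t, gam))
    return float(out) if out.ndim == 0 else out


def annual_death_probs(log_lambda, log_gamma, ages: np.ndarray) -> np.ndarray:
    """Vectorised per-cycle death probabilities for cycles starting at ``ages``.

    ``log_lambda``/``log_gamma`` may be scalars or draw vectors of shape (n,);
    the result has shape (len(ages), n) in the vector case, (len(ages),)
    otherwise.
    """
    lam = np.exp(np.atleast_1d(np.asarray(log_lambda, dtype=float)))
    gam = np.exp(np.atleast_1d(np.asarray(log_gamma, dtype=float)))
    a = np.asarray(ages, dtype=float)[:, None]
    h0 = lam[None, :] * np.power(a, gam[None, :])
    h1 = lam[None, :] * np.power(a + 1.0, gam[None, :])
    out = -np.expm1(h0 - h1)
    if np.isscalar(log_lambda) or np.asarray(log_lambda).ndim == 0:
        return out[:, 0]
    return out


# ---------------------------------------------------------------------------
# fitting


class NoEventsError(ValueError):
    """Raised when every record is censored, as for the PKU/MCD registries."""


@dataclass(frozen=True)
class SurvivalFit:
    family: str  # "weibull" | "exponential"
    params: WeibullParams
    loglik: float
    aic: float
    n_events: int
    n_censored: int

    @property
    def k(self) -> int:
        return 2 if self.family == "weibull" else 1


def _check_records(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if len(times) < 2:
        raise ValueError("at least 2 records required")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not events.any():
        raise NoEventsError("all records censored; the hazard is unidentifiable")
    return times, events


def _weibull_loglik(a: float, b: float, times: np.ndarray, events: np.ndarray) -> float:
    """Right-censored log-likelihood at log_lambda = a, log_gamma = b."""
    lam, gam = np.exp(a), np.exp(b)
    logt = np.log(times)
    return float(events.sum() * (a + b) + (gam - 1.0) * logt[events].sum()
                 - lam * np.power(times, gam).sum())


def fit_weibull(times, events) -> SurvivalFit:
    """Maximum-likelihood Weibull fit to right-censored records.

    ``events`` is truthy for a death, falsy for censoring.  The scale
    parameter is profiled out (lambda-hat = d / sum(t**gamma)) and the shape
    maximised in one dimension; standard errors come from the observed
    information of the full 2-parameter log-likelihood.
    """
    times, events = _check_records(times, events)
    d = int(events.sum())

    def profile_nll(b: float) -> float:
        gam = np.exp(b)
        T = np.power(times, gam).sum()
        a = np.log(d / T)
        return -_weibull_loglik(a, b, times, events)

    res = minimize_scalar(profile_nll, bounds=(-6.0, 4.0), method="bounded",
                          options={"xatol": 1e-10})
    b_hat = float(res.x)
    gam = np.exp(b_hat)
    a_hat = float(np.log(d / np.power(times, gam).sum()))
    ll = _weibull_loglik(a_hat, b_hat, times, events)

    hess = approx_hess(np.array([a_hat, b_hat]),
                       lambda x: -_weibull_loglik(x[0], x[1], times, events))
    cov = np.linalg.inv(hess)
    se_a, se_b = np.sqrt(np.diag(cov))

    return SurvivalFit(
        family="weibull",
        params=WeibullParams(_log_param(a_hat, se_a), _log_param(b_hat, se_b)),
        loglik=ll,
        aic=2 * 2 - 2 * ll,
        n_events=d,
        n_censored=int((~events).sum()),
    )


def _log_param(mean: float, se: float) -> ParamDist:
    from .params import Family
    return ParamDist(Family.lognormal, mean, float(se), log_scale=True)


def fit_exponential(times, events) -> SurvivalFit:
    """Constant-hazard (gamma = 1) fit: lambda-hat = events / total exposure."""
    times, events = _check_records(times, events)
    d = int(events.sum())
    lam = d / times.sum()
    a_hat = float(np.log(lam))
    ll = _weibull_loglik(a_hat, 0.0, times, events)
    return SurvivalFit(
        family="exponential",
        params=WeibullParams(_log_param(a_hat, 1.0 / np.sqrt(d)), fixed(0.0)),
        loglik=ll,
        aic=2 * 1 - 2 * ll,
        n_events=d,
        n_censored=int((~events).sum()),
    )


def select_by_aic(fits: list[SurvivalFit]) -> SurvivalFit:
    """Minimum-AIC fit; ties resolved toward the model with fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.k))
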