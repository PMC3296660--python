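"""Probability models for protein length and their maximum-likelihood fits.

Four candidate laws describe the bulk of a proteome's length distribution:

* ``gamma_free``   — gamma with free shape theta and rate alpha,
  f(z) = alpha^theta z^(theta-1) exp(-alpha z) / Gamma(theta);
* ``gamma_fixed2`` — the same with shape fixed at 2,
  f(z) = alpha^2 z exp(-alpha z);
* ``lognormal``    — f(z) = exp(-(log z - mu)^2 / (2 sigma^2)) / (z sigma sqrt(2 pi));
* ``sexp``         — hypoexponential, the sum of two independent exponential
  variables with rates alpha < beta,
  f(z) = alpha beta / (beta - alpha) (exp(-alpha z) - exp(-beta z)),
  which degenerates to ``gamma_fixed2`` as beta -> alpha.

A Pareto power law f(z) = a zm^a / z^(a+1) on z > zm models the extreme
right tail (very large proteins) above a configurable threshold.

Fitting subsets the sample to an open length range (default 0 < z < 1500)
and maximises the untruncated likelihood on that subset; models are ranked
by AIC = 2k - 2 log L on the identical filtered sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SexpParams",
    "GammaParams",
    "LognormalParams",
    "ParetoParams",
    "ModelFit",
    "ModelComparison",
    "ParetoTailFit",
    "NonIdentifiableError",
    "MODEL_ORDER",
    "density",
    "log_density",
    "cdf",
    "loglik",
    "fit_mle",
    "compare_models",
    "lognormal_moments",
    "pareto_mle",
    "fit_pareto_tail",
    "observed_information",
    "params_to_dict",
    "params_from_dict",
]

#: Candidate models in tie-break order: fewest estimated parameters first,
#: then a fixed conventional order so comparisons are deterministic.
MODEL_ORDER: tuple[str, ...] = ("gamma_fixed2", "sexp", "gamma_free", "lognormal")


class NonIdentifiableError(ValueError):
    """Raised when the data cannot identify the model parameters."""


@dataclass(frozen=True)
class SexpParams:
    """Rates of the two exponential components, canonicalised alpha <= beta."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("sexp rates must be positive")
        if self.alpha > self.beta:
            a, b = self.alpha, self.beta
            object.__setattr__(self, "alpha", b)
            object.__setattr__(self, "beta", a)

    @property
    def mean(self) -> float:
        return 1.0 / self.alpha + 1.0 / self.beta


@dataclass(frozen=True)
class GammaParams:
    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class LognormalParams:
    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if not self.sdlog > 0:
            raise ValueError("sdlog must be positive")

    @property
    def median(self) -> float:
        return math.exp(self.meanlog)

    @property
    def mean(self) -> float:
        return math.exp(self.meanlog + self.sdlog**2 / 2.0)


@dataclass(frozen=True)
class ParetoParams:
    zm: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.zm > 0 and self.shape > 0):
            raise ValueError("Pareto scale and shape must be positive")


@dataclass(frozen=True)
class ModelFit:
    """One model fitted to one sample: estimate, likelihood and AIC."""

    model: str
    params: object
    k: int
    loglik: float
    n: int
    fit_range: tuple[float, float] | None
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass(frozen=True)
class ModelComparison:
    """All candidate fits on one sample plus the AIC winner."""

    fits: Mapping[str, ModelFit]
    best_model: str

    @property
    def best_fit(self) -> ModelFit:
        return self.fits[self.best_model]


# relative rate gap below which the hypoexponential is evaluated through its
# gamma-shape-2 limit to avoid 0/0
_SEXP_DEGENERATE_RTOL = 1e-10


def _sexp_logpdf(alpha: float, beta: float, z: np.ndarray) -> np.ndarray:
    lo, hi = (alpha, beta) if alpha <= beta else (beta, alpha)
    d = hi - lo
    if d <= lo * _SEXP_DEGENERATE_RTOL:
        return 2.0 * np.log(lo) + np.log(z) - lo * z
    # f = lo*hi*exp(-lo z) * (1 - exp(-d z)) / d, written with expm1 so the
    # near-degenerate regime stays accurate
    return (
        np.log(lo)
        + np.log(hi)
        - lo * z
        + np.log(-np.expm1(-d * z))
        - np.log(d)
    )


def log_density(model: str, params: object, z) -> np.ndarray:
    """Log density of ``model`` at lengths ``z``; -inf outside the support."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, -np.inf)
    pos = z > 0
    zp = z[pos]
    if model == "gamma_free":
        th, al = params.shape, params.rate
        out[pos] = th * np.log(al) - special.gammaln(th) + (th - 1.0) * np.log(zp) - al * zp
    elif model == "gamma_fixed2":
        al = params.rate
        out[pos] = 2.0 * np.log(al) + np.log(zp) - al * zp
    elif model == "lognormal":
        mu, sg = params.meanlog, params.sdlog
        out[pos] = (
            -np.log(zp)
            - math.log(sg)
            - 0.5 * math.log(2.0 * math.pi)
            - (np.log(zp) - mu) ** 2 / (2.0 * sg**2)
        )
    elif model == "sexp":
        out[pos] = _sexp_logpdf(params.alpha, params.beta, zp)
    elif model == "pareto":
        a, zm = params.shape, params.zm
        sup = z > zm
        out[sup] = math.log(a) + a * math.log(zm) - (a + 1.0) * np.log(z[sup])
    else:
        raise ValueError(f"unknown model {model!r}")
    return out


def density(model: str, params: object, z) -> np.ndarray | float:
    """Probability density (per aa) of ``model`` at ``z``; 0 outside support."""
    scalar = np.isscalar(z)
    ld = log_density(model, params, np.atleast_1d(z))
    d = np.exp(ld)
    return float(d[0]) if scalar else d


def cdf(model: str, params: object, z) -> np.ndarray | float:
    """Cumulative distribution of ``model`` at ``z``."""
    scalar = np.isscalar(z)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.zeros(z.shape)
    pos = z > 0
    zp = z[pos]
    if model == "gamma_free":
        out[pos] = special.gammainc(params.shape, params.rate * zp)
    elif model == "gamma_fixed2":
        out[pos] = special.gammainc(2.0, params.rate * zp)
    elif model == "lognormal":
        out[pos] = stats.norm.cdf((np.log(zp) - params.meanlog) / params.sdlog)
    elif model == "sexp":
        a, b = params.alpha, params.beta
        if b - a <= a * _SEXP_DEGENERATE_RTOL:
            out[pos] = special.gammainc(2.0, a * zp)
        else:
            out[pos] = 1.0 - (b * np.exp(-a * zp) - a * np.exp(-b * zp)) / (b - a)
    elif model == "pareto":
        sup = z > params.zm
        out[sup] = 1.0 - (params.zm / z[sup]) ** params.shape
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(out[0]) if scalar else out


def loglik(model: str, params: object, z) -> float:
    """Total log-likelihood of the sample ``z`` under ``model``."""
    return float(np.sum(log_density(model, params, z)))


def lognormal_moments(params: LognormalParams) -> tuple[float, float]:
    """(mean, median) of the log-normal law in aa: e^(mu+sigma^2/2), e^mu."""
    return params.mean, params.median


def _apply_range(lengths, fit_range) -> np.ndarray:
    z = np.asarray(lengths, dtype=float).ravel()
    if fit_range is not None:
        lo, hi = fit_range
        z = z[(z > lo) & (z < hi)]
    return z


def _moment_init_gamma(z: np.ndarray) -> GammaParams:
    m, v = z.mean(), z.var(ddof=1)
    return GammaParams(shape=m * m / v, rate=m / v)


def _moment_init_sexp(z: np.ndarray) -> SexpParams:
    # match mean = 1/a + 1/b and variance = 1/a^2 + 1/b^2; the component
    # means 1/a, 1/b are then roots of x^2 - m x + (m^2 - v)/2
    m, v = z.mean(), z.var(ddof=1)
    disc = 2.0 * v - m * m
    if v < m * m and disc >= 0.0:
        root = math.sqrt(disc)
        u, w = (m - root) / 2.0, (m + root) / 2.0
        if u > 0:
            return SexpParams(alpha=1.0 / w, beta=1.0 / u)
    # no real positive solution: spread two rates around the shape-2 value
    return SexpParams(alpha=0.5 * (2.0 / m), beta=1.5 * (2.0 / m))


def fit_mle(model: str, lengths, fit_range: tuple[float, float] | None = (0.0, 1500.0)) -> ModelFit:
    """Fit one length model by maximum likelihood.

    Lengths outside the open ``fit_range`` are discarded and the untruncated
    likelihood is maximised on the remainder (no truncation correction).
    The log-normal uses its closed-form MLE (divisor-n variance of the
    logs); the other models are maximised numerically from moment-based
    starting values, and the returned log-likelihood is never below the
    starting value's.

    Raises
    ------
    ValueError
        Fewer than 10 lengths inside the range.
    NonIdentifiableError
        All in-range lengths identical.
    """
    if model not in MODEL_ORDER:
        raise ValueError(f"unknown model {model!r}")
    z = _apply_range(lengths, fit_range)
    if z.size < 10:
        raise ValueError(f"need >= 10 lengths inside the fit range, got {z.size}")
    if np.all(z == z[0]):
        raise NonIdentifiableError("all lengths equal; parameters not identifiable")
    n = int(z.size)

    if model == "lognormal":
        logs = np.log(z)
        mu = float(logs.mean())
        sg = float(np.sqrt(np.mean((logs - mu) ** 2)))
        params = LognormalParams(meanlog=mu, sdlog=sg)
        return ModelFit("lognormal", params, 2, loglik(model, params, z), n, fit_range, True)

    sum_z = float(z.sum())
    sum_log = float(np.log(z).sum())

    if model == "gamma_free":
        init = _moment_init_gamma(z)

        def negll(x):
            th, al = math.exp(x[0]), math.exp(x[1])
            return -(n * (th * math.log(al) - special.gammaln(th)) + (th - 1.0) * sum_log - al * sum_z)

        def grad(x):
            th, al = math.exp(x[0]), math.exp(x[1])
            d_th = n * (math.log(al) - special.digamma(th)) + sum_log
            d_al = n * th / al - sum_z
            return np.array([-th * d_th, -al * d_al])

        x0 = np.log([init.shape, init.rate])
        res = optimize.minimize(negll, x0, jac=grad, method="L-BFGS-B")
        params = GammaParams(shape=float(np.exp(res.x[0])), rate=float(np.exp(res.x[1])))
        converged = bool(res.success)
    elif model == "gamma_fixed2":
        m = z.mean()
        init = GammaParams(shape=2.0, rate=2.0 / m)

        def negll1(x):
            al = math.exp(x[0])
            return -(2.0 * n * math.log(al) + sum_log - al * sum_z)

        res = optimize.minimize(negll1, [math.log(init.rate)], method="L-BFGS-B")
        params = GammaParams(shape=2.0, rate=float(np.exp(res.x[0])))
        converged = bool(res.success)
    else:  # sexp
        init = _moment_init_sexp(z)

        def negll2(x):
            a, b = np.exp(x)
            return -float(np.sum(_sexp_logpdf(a, b, z)))

        x0 = np.log([init.alpha, init.beta])
        res = optimize.minimize(
            negll2, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        a, b = np.exp(res.x)
        params = SexpParams(alpha=float(a), beta=float(b))
        converged = bool(res.success)

    ll = loglik(model, params, z)
    ll_init = loglik(model, init, z)
    if not np.isfinite(ll) or ll < ll_init:
        # the optimiser must not do worse than its starting point; falling
        # back to the moment start is normal when it already solves the
        # score equation (gamma_fixed2: rate = 2/mean), so keep the
        # optimiser's convergence status unless it produced garbage
        if not np.isfinite(ll):
            converged = False
        params, ll = init, ll_init
    k = 1 if model == "gamma_fixed2" else 2
    return ModelFit(model, params, k, float(ll), n, fit_range, converged)


def compare_models(lengths, fit_range: tuple[float, float] | None = (0.0, 1500.0)) -> ModelComparison:
    """Fit all candidate models on the identical filtered sample, rank by AIC.

    Ties are broken fewest-parameters-first in :data:`MODEL_ORDER`;
    non-converged fits are excluded from winner selection with a warning.
    """
    z = _apply_range(lengths, fit_range)
    fits: dict[str, ModelFit] = {}
    for model in MODEL_ORDER:
        fit = fit_mle(model, z, fit_range=None)
        fits[model] = replace(fit, fit_range=fit_range)
    candidates = [m for m in MODEL_ORDER if fits[m].converged]
    if not candidates:
        raise RuntimeError("no model fit converged")
    for m in MODEL_ORDER:
        if not fits[m].converged:
            logger.warning("model %s did not converge; excluded from AIC selection", m)
    best = min(candidates, key=lambda m: (fits[m].aic, MODEL_ORDER.index(m)))
    return ModelComparison(fits=fits, best_model=best)


def pareto_mle(tail) -> ParetoParams:
    """Closed-form Pareto MLE on tail lengths: zm = min, shape = n / sum log(z/zm)."""
    t = np.asarray(tail, dtype=float)
    if t.size == 0:
        raise ValueError("empty tail")
    zm = float(t.min())
    denom = float(np.sum(np.log(t) - math.log(zm)))
    if denom <= 0.0:
        raise NonIdentifiableError("zero log-spread in tail; Pareto shape diverges")
    return ParetoParams(zm=zm, shape=t.size / denom)


@dataclass(frozen=True)
class ParetoTailFit:
    params: ParetoParams
    chi2: float
    df: int
    p_value: float
    n_tail: int


def fit_pareto_tail(lengths, threshold: float = 1500.0, min_tail: int = 30) -> ParetoTailFit:
    """Fit the Pareto law to lengths strictly above ``threshold``.

    Goodness of fit uses equal-probability bins under the fitted model
    (expected count >= 5 per bin), statistic sum (O-E)^2 / E with
    df = bins - 2 (one estimated shape; zm treated as a boundary).
    """
    z = np.asarray(lengths, dtype=float)
    tail = np.sort(z[z > threshold])
    if tail.size < min_tail:
        raise ValueError(f"need >= {min_tail} lengths above {threshold}, got {tail.size}")
    params = pareto_mle(tail)
    n = int(tail.size)
    n_bins = max(3, min(10, n // 5))
    # equal-probability edges: quantiles of the fitted Pareto
    qs = np.arange(1, n_bins) / n_bins
    edges = params.zm * (1.0 - qs) ** (-1.0 / params.shape)
    observed = np.diff(np.concatenate(([0], np.searchsorted(tail, edges, side="right"), [n])))
    expected = np.full(n_bins, n / n_bins)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = n_bins - 2
    p = float(stats.chi2.sf(stat, df))
    return ParetoTailFit(params=params, chi2=stat, df=df, p_value=p, n_tail=n)


def observed_information(model: str, params: object, lengths, rel_step: float = 1e-5) -> np.ndarray:
    """Observed information matrix (negative Hessian of the total
    log-likelihood) by central finite differences in the natural parameters.
    """
    z = np.asarray(lengths, dtype=float)
    theta = np.array(_params_values(model, params), dtype=float)
    p = theta.size

    def ll(v: np.ndarray) -> float:
        return loglik(model, _params_build(model, v), z)

    steps = np.maximum(np.abs(theta) * rel_step, 1e-12)
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            if i == j:
                val = (ll(theta + ei) - 2.0 * ll(theta) + ll(theta - ei)) / steps[i] ** 2
            else:
                val = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = val
    return -hess


_PARAM_FIELDS: dict[str, tuple[str, ...]] = {
    "gamma_free": ("shape", "rate"),
    "gamma_fixed2": ("rate",),
    "lognormal": ("meanlog", "sdlog"),
    "sexp": ("alpha", "beta"),
    "pareto": ("zm", "shape"),
}


def _params_values(model: str, params: object) -> tuple[float, ...]:
    return tuple(getattr(params, f) for f in _PARAM_FIELDS[model])


def _params_build(model: str, values: Sequence[float]) -> object:
    if model == "gamma_free":
        return GammaParams(shape=values[0], rate=values[1])
    if model == "gamma_fixed2":
        return GammaParams(shape=2.0, rate=values[0])
    if model == "lognormal":
        return LognormalParams(meanlog=values[0], sdlog=values[1])
    if model == "sexp":
        return SexpParams(alpha=values[0], beta=values[1])
    if model == "pareto":
        return ParetoParams(zm=values[0], shape=values[1])
    raise ValueError(f"unknown model {model!r}")


def params_to_dict(model: str, params: object) -> dict[str, float]:
    """JSON-friendly mapping of a parameter object's fields."""
    return {f: float(getattr(params, f)) for f in _PARAM_FIELDS[model]}


def params_from_dict(model: str, d: Mapping[str, float]) -> object:
    """Rebuild a parameter object from :func:`params_to_dict` output."""
    return _params_build(model, [d[f] for f in _PARAM_FIELDS[model]])
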