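"""Inference on the gamma shape parameter.

The free-shape gamma MLE is asymptotically normal; its standard error comes
from the information matrix, whose per-observation form for the
(shape theta, rate alpha) parametrisation is

    I(theta, alpha) = [[psi'(theta), -1/alpha],
                       [-1/alpha,    theta/alpha^2]],

so the asymptotic variance of the shape estimate is

    [I^-1]_theta,theta / n = theta / (theta psi'(theta) - 1) / n.

For the gamma family in this parametrisation the observed information
(negative Hessian of the total log-likelihood at the MLE) contains no data
terms, so observed and expected information coincide exactly.

Per-species shape estimates theta_j with standard errors sigma_j are pooled
as theta_bar = mean(theta_j) with variance sum(sigma_j^2) / J^2, assuming
independence across species, and tested against a hypothesised value
(theta0 = 2 by default) with a two-sided normal test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .distributions import ModelFit

__all__ = [
    "ShapeTestResult",
    "gamma_shape_asymptotic_variance",
    "shape_standard_error",
    "pooled_shape_test",
]


@dataclass(frozen=True)
class ShapeTestResult:
    """Pooled cross-species test of H0: theta = theta0."""

    theta_bar: float
    pooled_variance: float
    z_stat: float
    p_value: float
    theta0: float
    J: int


def gamma_shape_asymptotic_variance(shape: float) -> float:
    """Per-observation asymptotic variance of the shape MLE:
    theta / (theta psi'(theta) - 1)."""
    if shape <= 0:
        raise ValueError("shape must be positive")
    denom = shape * special.polygamma(1, shape) - 1.0
    return float(shape / denom)


def shape_standard_error(fit: ModelFit) -> float:
    """Standard error of the shape estimate from the information matrix."""
    if fit.model != "gamma_free":
        raise ValueError("shape_standard_error requires a gamma_free fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    th, al = fit.params.shape, fit.params.rate
    info = fit.n * np.array(
        [[special.polygamma(1, th), -1.0 / al], [-1.0 / al, th / al**2]]
    )
    det = np.linalg.det(info)
    if not np.isfinite(det) or det <= 0:
        raise np.linalg.LinAlgError("singular information matrix")
    inv = np.linalg.inv(info)
    return float(np.sqrt(inv[0, 0]))


def pooled_shape_test(
    shape_estimates,
    ses,
    theta0: float = 2.0,
    weighted: bool = False,
) -> ShapeTestResult:
    """Pool per-species shape estimates and test H0: theta = theta0.

    The default pools species unweighted: theta_bar is the plain mean and
    the pooled variance is sum(sigma_j^2) / J^2.  ``weighted=True`` uses
    inverse-variance weights instead (not the default, since the unweighted
    mean treats species as exchangeable regardless of proteome size).
    """
    th = np.asarray(shape_estimates, dtype=float).ravel()
    se = np.asarray(ses, dtype=float).ravel()
    if th.size != se.size:
        raise ValueError("shape_estimates and ses must have equal length")
    J = int(th.size)
    if J < 2:
        raise ValueError("need at least 2 species")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    if weighted:
        w = 1.0 / se**2
        theta_bar = float(np.sum(w * th) / np.sum(w))
        pooled_var = float(1.0 / np.sum(w))
    else:
        theta_bar = float(th.mean())
        pooled_var = float(np.sum(se**2) / J**2)
    z = (theta_bar - theta0) / np.sqrt(pooled_var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ShapeTestResult(
        theta_bar=theta_bar,
        pooled_variance=pooled_var,
        z_stat=float(z),
        p_value=p,
        theta0=theta0,
        J=J,
    )
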