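"""Numeric posterior over the independent variable of a calibration model.

Given one or more observed responses, the posterior of the independent
variable under a uniform prior on a user-specified interval is

    p(x | y_obs) = L(x | y_obs) / integral_a^b L(x | y_obs) dx

with L the product of the calibration model's per-observation likelihoods.
The posterior is evaluated on a grid that is densely resolved around the
probability mass: a coarse pass (10 000 points on [a, b]) locates the
99.999% equal-tailed region, a fine pass (100 000 points inside it) yields
the returned density/CDF, from which the median, the equal-tailed interval
(ETI) and the highest-density interval (HDI) are read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import integrate, optimize, stats

from .calibration import CalibrationModel

__all__ = ["InferenceResult", "infer_independent", "eti_from_cdf", "hdi_from_cdf"]

N_COARSE = 10_000
N_FINE = 100_000
BRACKET_PROB = 0.99999


@dataclass
class InferenceResult:
    """Gridded posterior of the independent variable with interval summaries."""

    x_grid: np.ndarray
    density: np.ndarray
    median: float
    eti: Tuple[float, float]
    hdi: Tuple[float, float]
    ci_prob: float


def _loglik_grid(model: CalibrationModel, grid: np.ndarray, y_obs: np.ndarray) -> np.ndarray:
    """Summed log-likelihood of all observations at each grid point."""
    d = model.predict_dependent(grid)
    mu = np.atleast_1d(d.mu)[:, None]
    scale = np.atleast_1d(d.scale)[:, None]
    if d.nu is not None:
        ll = stats.t.logpdf(y_obs[None, :], df=d.nu, loc=mu, scale=scale)
    else:
        ll = stats.norm.logpdf(y_obs[None, :], loc=mu, scale=scale)
    return ll.sum(axis=1)


def _density_cdf(model, grid, y_obs):
    """Normalized density and CDF on a grid, accumulated in log space."""
    ll = _loglik_grid(model, grid, y_obs)
    m = np.max(ll)
    if not np.isfinite(m):
        raise ValueError(
            "zero total likelihood mass in the requested interval; "
            "observations may be incompatible with the bounds"
        )
    dens = np.exp(ll - m)
    cdf = np.concatenate([[0.0], integrate.cumulative_trapezoid(dens, grid)])
    total = cdf[-1]
    if total <= 0:
        raise ValueError("zero total likelihood mass in the requested interval")
    return dens / total, cdf / total


def infer_independent(
    model: CalibrationModel,
    y_obs,
    lower: float = None,
    upper: float = None,
    ci_prob: float = 0.9,
) -> InferenceResult:
    """Posterior of the independent variable given observed responses.

    ``lower``/``upper`` bound the uniform prior; when omitted they default to
    the calibrated independent range extended by 10% on each side.
    """
    if not 0 < ci_prob < 1:
        raise ValueError("ci_prob must be in (0, 1)")
    y_obs = np.atleast_1d(np.asarray(y_obs, dtype=float))
    if y_obs.size < 1:
        raise ValueError("need at least one observation")
    if lower is None or upper is None:
        lo, hi = model.calibrated_range
        pad = 0.1 * (hi - lo)
        if lower is None:
            lower = lo - pad
            if lo >= 0 and lower < 0:
                lower = 0.0  # nonnegative quantity: keep the prior physical
        upper = hi + pad if upper is None else upper
    if not lower < upper:
        raise ValueError("lower must be < upper")
    if model.noise.trend == "log_independent_asymmetric_logistic" and lower <= 0:
        lower = 1e-10 * upper  # log-trend domain is x > 0

    # coarse pass: bracket the probability mass
    coarse = np.linspace(lower, upper, N_COARSE)
    _, cdf_c = _density_cdf(model, coarse, y_obs)
    tail = (1.0 - BRACKET_PROB) / 2.0
    i = max(int(np.searchsorted(cdf_c, tail, side="right")) - 1, 0)
    j = min(int(np.searchsorted(cdf_c, 1.0 - tail, side="left")), N_COARSE - 1)
    if j <= i + 1:
        i, j = max(i - 1, 0), min(i + 2, N_COARSE - 1)

    # fine pass inside the bracket
    fine = np.linspace(coarse[i], coarse[j], N_FINE)
    dens, cdf = _density_cdf(model, fine, y_obs)

    median = float(np.interp(0.5, cdf, fine))
    eti = eti_from_cdf(fine, cdf, ci_prob)
    hdi = hdi_from_cdf(fine, cdf, ci_prob)
    return InferenceResult(
        x_grid=fine, density=dens, median=median, eti=eti, hdi=hdi, ci_prob=ci_prob
    )


def _check_cdf(x_grid, cdf):
    x_grid = np.asarray(x_grid, dtype=float)
    cdf = np.asarray(cdf, dtype=float)
    if x_grid.shape != cdf.shape or x_grid.ndim != 1:
        raise ValueError("x_grid and cdf must be 1-D and equally long")
    if np.any(np.diff(cdf) < -1e-12):
        raise ValueError("cdf must be nondecreasing")
    if not (abs(cdf[0]) < 1e-3 and abs(cdf[-1] - 1.0) < 1e-3):
        raise ValueError("cdf must run from ~0 to ~1")
    return x_grid, cdf


def eti_from_cdf(x_grid, cdf, ci_prob: float) -> Tuple[float, float]:
    """Equal-tailed interval: grid points with CDF nearest the tail levels."""
    x_grid, cdf = _check_cdf(x_grid, cdf)
    if not 0 < ci_prob <= 1:
        raise ValueError("ci_prob must be in (0, 1]")
    lo_level = (1.0 - ci_prob) / 2.0
    hi_level = 1.0 - lo_level
    i = int(np.argmin(np.abs(cdf - lo_level)))
    j = int(np.argmin(np.abs(cdf - hi_level)))
    return float(x_grid[i]), float(x_grid[j])


def hdi_from_cdf(x_grid, cdf, ci_prob: float) -> Tuple[float, float]:
    """Highest-density interval: shortest [a, a+d] with CDF(a+d)-CDF(a) >= ci_prob.

    1-D bounded minimization of the interpolated interval width over the
    lower bound ``a``.
    """
    x_grid, cdf = _check_cdf(x_grid, cdf)
    if not 0 < ci_prob < 1 + 1e-12:
        raise ValueError("ci_prob must be a probability")
    if ci_prob > cdf[-1] + 1e-9:
        raise ValueError("requested ci_prob exceeds total probability mass")
    # strictly increasing subset for the inverse CDF
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    cdf_inc, x_inc = cdf[keep], x_grid[keep]

    def upper_of(a):
        return np.interp(np.interp(a, x_inc, cdf_inc) + ci_prob, cdf_inc, x_inc)

    a_max = float(np.interp(1.0 - ci_prob, cdf_inc, x_inc))
    a_min = float(x_grid[0])
    if a_max <= a_min:
        return a_min, float(upper_of(a_min))
    # multimodal densities make the width multimodal in a: coarse pre-scan,
    # then a bounded local refinement around the best coarse cell
    coarse = np.linspace(a_min, a_max, 512)
    widths = upper_of(coarse) - coarse
    k = int(np.argmin(widths))
    lo_k = coarse[max(k - 1, 0)]
    hi_k = coarse[min(k + 1, coarse.size - 1)]
    a = float(coarse[k])
    if hi_k > lo_k:
        res = optimize.minimize_scalar(
            lambda a_: upper_of(a_) - a_,
            bounds=(lo_k, hi_k),
            method="bounded",
            options={"xatol": (x_grid[-1] - x_grid[0]) / x_grid.size / 10},
        )
        if upper_of(res.x) - res.x < upper_of(a) - a:
            a = float(res.x)
    for cand in (a_min, a_max):
        if upper_of(cand) - cand < upper_of(a) - a:
            a = cand
    return a, float(upper_of(a))
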