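"""Probabilistic calibration models.

A calibration model describes a measurement system as a conditional
probability distribution of the response (dependent variable) given the
quantity of interest (independent variable): a parametric *trend* maps the
independent variable to the location parameter ``mu``, the *scale* of the
distribution is a low-order polynomial in ``mu`` (heteroscedastic noise that
grows with the signal), and the noise family is either a location-scale
Student-t (robust against outliers; degree of freedom ``nu`` estimated as a
constant) or a normal distribution.

Parameters are estimated by maximum likelihood within box bounds.  A fitted
model can invert single observations (``predict_independent``), quantify
lack-of-fit via percentile occupancy, and round-trip through JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import __version__
from .curves import (
    AsymLogisticParams,
    asymmetric_logistic,
    log_independent_asymmetric_logistic,
    polynomial,
)

__all__ = [
    "NoiseSpec",
    "DistributionParams",
    "IndependentEstimate",
    "CalibrationModel",
    "CompatibilityError",
    "fit_mle",
    "make_model",
    "percentile_occupancy",
    "save_model",
    "load_model",
    "plot_model",
]

TRENDS = ("polynomial", "asymmetric_logistic", "log_independent_asymmetric_logistic")


class CompatibilityError(Exception):
    """Raised when a persisted model file is of an unexpected type/version."""


@dataclass(frozen=True)
class NoiseSpec:
    """Noise parametrization: family + trend + scale polynomial + df mode.

    family       : "student_t" or "normal"
    trend        : one of TRENDS ("polynomial" with ``trend_degree``)
    trend_degree : polynomial degree of the location trend (ignored for
                   logistic trends, which always have 5 parameters)
    scale_degree : degree of the polynomial scale(mu); 0 or 1
    df_mode      : "estimated_constant" (nu is the last theta entry) or
                   "fixed" (nu = df_value, not estimated)
    """

    family: str = "student_t"
    trend: str = "polynomial"
    trend_degree: int = 1
    scale_degree: int = 1
    df_mode: str = "estimated_constant"
    df_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("student_t", "normal"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.trend not in TRENDS:
            raise ValueError(f"unknown trend {self.trend!r}")
        if self.scale_degree not in (0, 1):
            raise ValueError("scale polynomial degree must be 0 or 1")
        if self.family == "student_t" and self.df_mode == "fixed":
            if self.df_value is None or not self.df_value > 0:
                raise ValueError("fixed df_mode requires df_value > 0")

    @property
    def trend_arity(self) -> int:
        if self.trend == "polynomial":
            return self.trend_degree + 1
        return 5

    @property
    def n_theta(self) -> int:
        n = self.trend_arity + self.scale_degree + 1
        if self.family == "student_t" and self.df_mode == "estimated_constant":
            n += 1
        return n

    @property
    def model_type(self) -> str:
        return f"{self.family}:{self.trend}:d{self.trend_degree}:scale{self.scale_degree}"


@dataclass
class DistributionParams:
    """Parameters of the predicted response distribution at one (or more) x."""

    mu: np.ndarray
    scale: np.ndarray
    nu: Optional[float] = None


class IndependentEstimate(NamedTuple):
    """Point estimate of the independent variable with a saturation flag."""

    x: float
    saturated: bool


@dataclass
class CalibrationModel:
    """Trend + noise calibration model with MLE machinery.

    ``theta`` is laid out as trend parameters, then scale-polynomial
    coefficients (constant first), then ``nu`` for Student-t models with
    estimated degree of freedom.
    """

    independent_key: str = "independent"
    dependent_key: str = "dependent"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    theta: Optional[np.ndarray] = None
    theta_guess: Optional[np.ndarray] = None
    theta_bounds: Optional[list] = None
    cal_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    cal_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    version_tag: str = __version__
    fit_info: dict = field(default_factory=dict)

    # -- parameter vector slicing -------------------------------------------------
    def _split_theta(self, theta=None):
        theta = np.asarray(self.theta if theta is None else theta, dtype=float)
        if theta.size != self.noise.n_theta:
            raise ValueError(
                f"theta has {theta.size} entries, model requires {self.noise.n_theta}"
            )
        a = self.noise.trend_arity
        b = a + self.noise.scale_degree + 1
        trend = theta[:a]
        scale = theta[a:b]
        if self.noise.family == "student_t":
            nu = self.noise.df_value if self.noise.df_mode == "fixed" else theta[b]
        else:
            nu = None
        return trend, scale, nu

    def _trend_mu(self, x, trend_params):
        if self.noise.trend == "polynomial":
            return polynomial(x, trend_params)
        p = AsymLogisticParams(*trend_params)
        if self.noise.trend == "asymmetric_logistic":
            return asymmetric_logistic(x, p)
        return log_independent_asymmetric_logistic(x, p)

    # -- core operations ----------------------------------------------------------
    def predict_dependent(self, x, theta=None) -> DistributionParams:
        """Predict the response distribution parameters at ``x``."""
        trend, scale_coeffs, nu = self._split_theta(theta)
        mu = self._trend_mu(x, trend)
        scale = polynomial(mu, scale_coeffs)
        if np.any(np.asarray(scale) <= 0):
            raise ValueError("scale polynomial evaluated non-positive; invalid theta")
        return DistributionParams(mu=mu, scale=scale, nu=nu)

    def loglikelihood(self, x, y, theta=None) -> float:
        """Sum of log-likelihoods of paired observations (x_i, y_i)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs to loglikelihood")
        d = self.predict_dependent(x, theta)
        if d.nu is not None:
            return float(np.sum(stats.t.logpdf(y, df=d.nu, loc=d.mu, scale=d.scale)))
        return float(np.sum(stats.norm.logpdf(y, loc=d.mu, scale=d.scale)))

    def objective(self, x, y):
        """Return theta -> negative loglikelihood (for minimizers)."""

        def neg_ll(theta):
            try:
                return -self.loglikelihood(x, y, theta)
            except (ValueError, FloatingPointError):
                return np.inf

        return neg_ll

    @property
    def calibrated_range(self):
        if self.cal_x.size == 0:
            raise ValueError("model has no calibration data; no calibrated range")
        return float(np.min(self.cal_x)), float(np.max(self.cal_x))

    def predict_independent(self, y: float, bounds=None) -> IndependentEstimate:
        """Invert a single observation through the (monotone) trend.

        For a strictly monotone trend the single-observation MLE of the
        independent variable is the trend inverse of ``y``.  Observations
        outside the calibrated response range are clipped to the nearest
        range endpoint and flagged as saturated.
        """
        lo, hi = bounds if bounds is not None else self.calibrated_range
        trend, _, _ = self._split_theta()
        mu_lo = float(self._trend_mu(lo, trend))
        mu_hi = float(self._trend_mu(hi, trend))
        y_min, y_max = min(mu_lo, mu_hi), max(mu_lo, mu_hi)
        increasing = mu_hi >= mu_lo
        if y <= y_min:
            return IndependentEstimate(lo if increasing else hi, True)
        if y >= y_max:
            return IndependentEstimate(hi if increasing else lo, True)
        root = optimize.brentq(
            lambda x: float(self._trend_mu(x, trend)) - y, lo, hi, xtol=1e-12
        )
        return IndependentEstimate(float(root), False)


def percentile_occupancy(model: CalibrationModel, x, y, n_bins: int = 10) -> np.ndarray:
    """Count observations per percentile bin of their predicted distributions.

    For a well-specified model the CDF values of the observations are
    uniform on [0, 1]; systematic over/under-occupancy of bins diagnoses
    lack-of-fit of trend, spread or tail weight.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    d = model.predict_dependent(x)
    if d.nu is not None:
        u = stats.t.cdf(y, df=d.nu, loc=d.mu, scale=d.scale)
    else:
        u = stats.norm.cdf(y, loc=d.mu, scale=d.scale)
    counts, _ = np.histogram(u, bins=n_bins, range=(0.0, 1.0))
    return counts


def fit_mle(
    model: CalibrationModel,
    x,
    y,
    n_restarts: int = 0,
    seed: int = 0,
) -> CalibrationModel:
    """Maximum-likelihood fit of ``model`` to paired calibration data.

    Bound-constrained local optimization from ``theta_guess``; optionally
    ``n_restarts`` additional starts drawn uniformly within the bounds
    (seeded).  The returned model stores the calibration data, and parameters
    that ended up at a bound are flagged in ``fit_info``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if model.theta_guess is None or model.theta_bounds is None:
        raise ValueError("theta_guess and theta_bounds must be set before fitting")
    if x.size < model.noise.n_theta + 1:
        raise ValueError("need at least len(theta)+1 calibration points")
    neg_ll = model.objective(x, y)
    bounds = [tuple(b) for b in model.theta_bounds]
    rng = np.random.default_rng(seed)
    starts = [np.asarray(model.theta_guess, dtype=float)]
    for _ in range(n_restarts):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))
    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, bounds=bounds, method="L-BFGS-B")
        # simplex polish: robust to the kinks the box constraints introduce
        res2 = optimize.minimize(
            neg_ll,
            res.x,
            bounds=bounds,
            method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-10},
        )
        res = res2 if res2.fun < res.fun else res
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, dtype=float)
    at_bound = [
        i
        for i, (lo, hi) in enumerate(bounds)
        if np.isclose(theta[i], lo, atol=1e-10) or np.isclose(theta[i], hi, atol=1e-10)
    ]
    fitted = CalibrationModel(
        independent_key=model.independent_key,
        dependent_key=model.dependent_key,
        noise=model.noise,
        theta=theta,
        theta_guess=np.asarray(model.theta_guess, dtype=float),
        theta_bounds=bounds,
        cal_x=x.copy(),
        cal_y=y.copy(),
        version_tag=__version__,
        fit_info={
            "converged": bool(best.success),
            "neg_loglikelihood": float(best.fun),
            "parameters_at_bound": at_bound,
        },
    )
    if not best.success:
        warnings.warn(f"optimizer did not report convergence: {best.message}")
    return fitted


def make_model(
    x,
    y,
    trend: str = "polynomial",
    trend_degree: int = 1,
    scale_degree: int = 1,
    family: str = "student_t",
    independent_key: str = "independent",
    dependent_key: str = "dependent",
) -> CalibrationModel:
    """Construct an unfitted model with data-driven guesses and bounds.

    The intuitive logistic parametrization makes this straightforward: limits
    from the response range, inflection near the middle of the (log-)range,
    slope from the overall rise.  ``nu`` is constrained to [1, 100].
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    noise = NoiseSpec(
        family=family, trend=trend, trend_degree=trend_degree, scale_degree=scale_degree
    )
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span = max(y_hi - y_lo, 1e-6)
    if trend == "polynomial":
        coeffs = np.polynomial.polynomial.polyfit(x, y, trend_degree)
        guess_t = list(coeffs)
        bounds_t = [(-10 * abs(c) - 10 * span - 1, 10 * abs(c) + 10 * span + 1) for c in coeffs]
    else:
        xs = np.log10(x[x > 0]) if trend == "log_independent_asymmetric_logistic" else x
        ys = y[x > 0] if trend == "log_independent_asymmetric_logistic" else y
        order = np.argsort(xs)
        xs_s, ys_s = xs[order], ys[order]
        x_lo, x_hi = float(xs_s[0]), float(xs_s[-1])
        x_span = max(x_hi - x_lo, 1e-6)
        increasing = float(ys_s[-3:].mean()) >= float(ys_s[:3].mean())
        # inflection guess: where the response crosses the midpoint
        y_mid = 0.5 * (y_lo + y_hi)
        crossings = np.nonzero(np.diff(np.sign(ys_s - y_mid)))[0]
        i_x = float(xs_s[crossings[0]]) if crossings.size else 0.5 * (x_lo + x_hi)
        # slope guess: linear fit through the central response band
        central = (ys_s > y_lo + 0.25 * span) & (ys_s < y_hi - 0.25 * span)
        if central.sum() >= 2 and np.ptp(xs_s[central]) > 0:
            slope = float(np.polyfit(xs_s[central], ys_s[central], 1)[0])
        else:
            slope = (span / x_span * 2) * (1 if increasing else -1)
        if slope == 0:
            slope = span / x_span * (1 if increasing else -1)
        s_mag = abs(slope)
        guess_t = [y_lo, y_hi, i_x, slope, 0.0] if increasing else [y_hi, y_lo, i_x, slope, 0.0]
        lim_lo = (y_lo - span, y_lo + 0.5 * span)
        lim_hi = (y_hi - 0.5 * span, y_hi + 3 * span)
        bounds_t = [
            lim_lo if increasing else lim_hi,
            lim_hi if increasing else lim_lo,
            (x_lo - x_span, x_hi + x_span),
            (s_mag / 100, s_mag * 100) if slope > 0 else (-s_mag * 100, -s_mag / 100),
            (-4.0, 4.0),
        ]
    scale0 = max(0.05 * span, 1e-6)
    guess_s = [scale0] + [0.01] * scale_degree
    bounds_s = [(1e-9, 10 * span)] + [(0.0, 1.0)] * scale_degree
    guess = guess_t + guess_s
    bounds = bounds_t + bounds_s
    if family == "student_t":
        guess += [5.0]
        bounds += [(1.0, 100.0)]  # nu >= 1 keeps the likelihood well-behaved
    return CalibrationModel(
        independent_key=independent_key,
        dependent_key=dependent_key,
        noise=noise,
        theta_guess=np.asarray(guess, dtype=float),
        theta_bounds=bounds,
    )


# -- persistence -------------------------------------------------------------------


def save_model(model: CalibrationModel, path) -> None:
    """Persist a fitted model (parameters, bounds, data, provenance) as JSON."""
    if model.theta is None:
        raise ValueError("cannot save an unfitted model (theta is None)")
    payload = {
        "model_type": model.noise.model_type,
        "version": model.version_tag,
        "independent_key": model.independent_key,
        "dependent_key": model.dependent_key,
        "noise": {
            "family": model.noise.family,
            "trend": model.noise.trend,
            "trend_degree": model.noise.trend_degree,
            "scale_degree": model.noise.scale_degree,
            "df_mode": model.noise.df_mode,
            "df_value": model.noise.df_value,
            "log_base": 10,
        },
        "theta": list(map(float, model.theta)),
        "theta_guess": list(map(float, model.theta_guess))
        if model.theta_guess is not None
        else None,
        "theta_bounds": [list(map(float, b)) for b in model.theta_bounds]
        if model.theta_bounds is not None
        else None,
        "cal_x": list(map(float, model.cal_x)),
        "cal_y": list(map(float, model.cal_y)),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path, expected_type: Optional[str] = None) -> CalibrationModel:
    """Load a model from JSON, checking model-type and version compatibility."""
    payload = json.loads(Path(path).read_text())
    ns = payload["noise"]
    noise = NoiseSpec(
        family=ns["family"],
        trend=ns["trend"],
        trend_degree=int(ns.get("trend_degree", 1)),
        scale_degree=int(ns["scale_degree"]),
        df_mode=ns.get("df_mode", "estimated_constant"),
        df_value=ns.get("df_value"),
    )
    stored_type = payload.get("model_type")
    if stored_type != noise.model_type:
        raise CompatibilityError(
            f"model-type mismatch: file says {stored_type!r}, "
            f"noise spec implies {noise.model_type!r}"
        )
    if expected_type is not None and stored_type != expected_type:
        raise CompatibilityError(
            f"expected model type {expected_type!r}, file contains {stored_type!r}"
        )
    version = payload.get("version", "")
    if version.split(".")[0] != __version__.split(".")[0]:
        raise CompatibilityError(
            f"file written by incompatible version {version!r} (this is {__version__})"
        )
    cal_x = np.asarray(payload.get("cal_x") or [], dtype=float)
    cal_y = np.asarray(payload.get("cal_y") or [], dtype=float)
    if cal_x.size == 0 or cal_y.size == 0:
        warnings.warn("model file has no calibration data; calibrated range unknown")
    return CalibrationModel(
        independent_key=payload["independent_key"],
        dependent_key=payload["dependent_key"],
        noise=noise,
        theta=np.asarray(payload["theta"], dtype=float),
        theta_guess=np.asarray(payload["theta_guess"], dtype=float)
        if payload.get("theta_guess") is not None
        else None,
        theta_bounds=[tuple(b) for b in payload["theta_bounds"]]
        if payload.get("theta_bounds") is not None
        else None,
        cal_x=cal_x,
        cal_y=cal_y,
        version_tag=version,
    )


def plot_model(model: CalibrationModel, band_levels=(0.68, 0.90, 0.95)):
    """Three-panel diagnostic: data + likelihood bands, log-x view, residuals."""
    import matplotlib.pyplot as plt

    x, y = model.cal_x, model.cal_y
    if x.size == 0:
        raise ValueError("model has no calibration data to plot")
    lo, hi = model.calibrated_range
    grid = np.linspace(lo, hi, 500) if lo <= 0 else np.geomspace(lo, hi, 500)
    d = model.predict_dependent(grid)
    fig, axs = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, logx in zip(axs[:2], (False, True)):
        for p in sorted(band_levels, reverse=True):
            q = 0.5 + p / 2
            if d.nu is not None:
                w = stats.t.ppf(q, df=d.nu, loc=0, scale=d.scale)
            else:
                w = stats.norm.ppf(q, loc=0, scale=d.scale)
            ax.fill_between(grid, d.mu - w, d.mu + w, alpha=0.25, color="C2", lw=0)
        ax.plot(grid, d.mu, color="C2")
        ax.scatter(x, y, s=8, color="k", zorder=3)
        if logx and lo > 0:
            ax.set_xscale("log")
        ax.set_xlabel(model.independent_key)
        ax.set_ylabel(model.dependent_key)
    pred = model.predict_dependent(x)
    axs[2].axhline(0, color="C2")
    axs[2].scatter(x, (y - pred.mu) / pred.mu, s=8, color="k")
    axs[2].set_xlabel(model.independent_key)
    axs[2].set_ylabel("relative residual")
    fig.tight_layout()
    return fig
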