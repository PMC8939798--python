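"""Parametric trend functions for calibration models.

The central curve is the five-parameter asymmetric logistic (generalized
logistic / Richards curve) in an *intuitive* parametrization: lower limit
``L_L``, upper limit ``L_U``, inflection-point x-coordinate ``I_x``, slope at
the inflection point ``S`` and an asymmetry parameter ``c``.  Each of the five
parameters can be changed without affecting the others, which makes guesses
and bounds for curve fitting straightforward to specify.  The classic form

    f(x) = L_L + (L_U - L_L) * (1 + exp(-B*(m - x)))**(-1/v),    v > 0

is structurally non-identifiable in (B, m, v); :func:`to_intuitive` converts
it exactly into the intuitive parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AsymLogisticParams",
    "ClassicAsymLogisticParams",
    "asymmetric_logistic",
    "classic_asymmetric_logistic",
    "to_intuitive",
    "log_independent_asymmetric_logistic",
    "polynomial",
]

# exponent clip: exp(+-500) is finite in float64, beyond saturates the curve
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class AsymLogisticParams:
    """Intuitive parametrization of the 5-parameter asymmetric logistic.

    L_L, L_U : lower/upper limit (response units)
    I_x      : x-coordinate of the inflection point (independent units)
    S        : slope at the inflection point
    c        : asymmetry; at c=0 the inflection ordinate is (L_L+L_U)/2,
               c>0 moves it towards L_U, c<0 towards L_L
    """

    L_L: float
    L_U: float
    I_x: float
    S: float
    c: float

    def __post_init__(self) -> None:
        vals = (self.L_L, self.L_U, self.I_x, self.S, self.c)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite asymmetric-logistic parameters: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L_L, self.L_U, self.I_x, self.S, self.c])


@dataclass(frozen=True)
class ClassicAsymLogisticParams:
    """Classic parametrization (L_L, L_U, B, m, v) with v > 0."""

    L_L: float
    L_U: float
    B: float
    m: float
    v: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"v must be > 0, got {self.v}")


def asymmetric_logistic(x, p: AsymLogisticParams):
    """Evaluate the asymmetric logistic in its intuitive parametrization.

    Common subexpressions (s0..s3) are computed once per call.  Exponent
    overflow is clipped so that extreme ``x`` saturate to the corresponding
    limit instead of producing non-finite output.
    """
    x = np.asarray(x, dtype=float)
    L_L, L_U, I_x, S, c = p.L_L, p.L_U, p.I_x, p.S, p.c
    s0 = np.exp(c) + 1.0
    s1 = np.exp(-c)
    s2 = s0 ** (s0 * s1)
    s3 = S / (L_U - L_L)
    z = np.clip(s2 * s3 * (I_x - x) + c, -_EXP_CLIP, _EXP_CLIP)
    # (1 + e^z)^(-s1) evaluated in log space for numerical robustness
    log_g = np.clip(-s1 * np.logaddexp(0.0, z), -_EXP_CLIP, _EXP_CLIP)
    out = L_L + (L_U - L_L) * np.exp(log_g)
    return out if out.ndim else float(out)


def classic_asymmetric_logistic(x, p: ClassicAsymLogisticParams):
    """Evaluate the classic form L_L + (L_U-L_L)*(1 + e^{-B(m-x)})^{-1/v}."""
    if not p.v > 0:
        raise ValueError(f"v must be > 0, got {p.v}")
    x = np.asarray(x, dtype=float)
    z = np.clip(-p.B * (p.m - x), -_EXP_CLIP, _EXP_CLIP)
    log_g = np.clip(-np.logaddexp(0.0, z) / p.v, -_EXP_CLIP, _EXP_CLIP)
    out = p.L_L + (p.L_U - p.L_L) * np.exp(log_g)
    return out if out.ndim else float(out)


def to_intuitive(p: ClassicAsymLogisticParams) -> AsymLogisticParams:
    """Convert classic (L_L, L_U, B, m, v) to (L_L, L_U, I_x, S, c).

    The inflection point of the classic curve sits where e^{B(x-m)} = v,
    hence I_x = m + ln(v)/B; the slope there is
    S = -B (L_U - L_L) (1+v)^{-(v+1)/v}, and the asymmetry is c = ln(v).
    """
    if not p.v > 0:
        raise ValueError(f"v must be > 0, got {p.v}")
    c = np.log(p.v)
    I_x = p.m + np.log(p.v) / p.B
    S = -p.B * (p.L_U - p.L_L) * (1.0 + p.v) ** (-(p.v + 1.0) / p.v)
    return AsymLogisticParams(L_L=p.L_L, L_U=p.L_U, I_x=float(I_x), S=float(S), c=float(c))


def log_independent_asymmetric_logistic(x, p: AsymLogisticParams):
    """Asymmetric logistic applied to log10 of the independent variable.

    Used e.g. for biomass/backscatter calibrations where the response is
    logistic in the logarithm of the cell dry weight.  Requires x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log-independent trend requires x > 0")
    out = asymmetric_logistic(np.log10(x), p)
    return out if np.ndim(out) else float(out)


def polynomial(x, coeffs: Sequence[float]):
    """Evaluate a polynomial with the constant term first (Horner scheme)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 1 or coeffs.size < 1:
        raise ValueError("coefficient list must contain at least one entry")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for a in coeffs[::-1]:
        out = out * x + a
    return out if out.ndim else float(out)
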