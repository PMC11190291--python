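"""Complementary Bell Weibull (CBellW) distribution.

The CBellW law arises by compounding a Weibull baseline with a
zero-truncated Bell-distributed number of complementary (parallel) risks:
the observed lifetime is the maximum of N i.i.d. Weibull lifetimes where N
follows a zero-truncated Bell distribution with parameter ``lam``.  With
Weibull baseline cdf ``G(x) = 1 - exp(-(x/alpha)**beta)`` the cdf is

    F(x) = (exp(e**(lam*G(x)) - 1) - 1) / (exp(e**lam - 1) - 1)

All evaluations run through log-space primitives so that the doubly
exponential terms stay finite for ``lam`` well beyond the values met in
practice (the normalising exponent ``e**lam - 1`` overflows the naive
formula already for ``lam`` around 6.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "CBellWParams",
    "cdf",
    "pdf",
    "log_pdf",
    "survival",
    "hazard",
    "quantile",
    "rvs",
]

# exp(y) overflows double precision near y = 709.78; stay clear of it
_EXP_SAFE = 690.0


@dataclass(frozen=True)
class CBellWParams:
    """Parameter triple of the CBellW distribution.

    alpha : scale (same units as the data), > 0
    beta  : Weibull shape, > 0
    lam   : Bell (compounding) parameter, > 0
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite real, got {v!r}")
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        # store as plain floats
        object.__setattr__(self, "alpha", float(self.alpha))
        object.__setattr__(self, "beta", float(self.beta))
        object.__setattr__(self, "lam", float(self.lam))

    @property
    def a_max(self) -> float:
        """The normalising exponent A(inf) = e**lam - 1."""
        return math.expm1(self.lam)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.lam)


def _as_params(params) -> CBellWParams:
    if isinstance(params, CBellWParams):
        return params
    if isinstance(params, Iterable):
        return CBellWParams(*params)
    raise TypeError(f"cannot interpret {params!r} as CBellW parameters")


def _log_expm1(y):
    """log(exp(y) - 1) without overflow, elementwise for y > 0."""
    y = np.asarray(y, dtype=float)
    small = y < _EXP_SAFE
    out = np.where(small, np.log(np.expm1(np.where(small, y, 1.0))), 0.0)
    out = np.where(small, out, y + np.log1p(-np.exp(-np.maximum(y, 1.0))))
    return out


def _weibull_log_g(x, alpha: float, beta: float):
    """Log pdf of the Weibull baseline."""
    x = np.asarray(x, dtype=float)
    z = (x / alpha) ** beta
    return math.log(beta) - beta * math.log(alpha) + (beta - 1.0) * np.log(x) - z


def _kernel_a(x, p: CBellWParams):
    """A(x) = e**(lam*G(x)) - 1, the cdf numerator exponent."""
    x = np.asarray(x, dtype=float)
    g = -np.expm1(-((x / p.alpha) ** p.beta))  # Weibull cdf, stable near 0
    return np.expm1(p.lam * g)


def _check_x(x, allow_zero: bool = True):
    x = np.asarray(x, dtype=float)
    lo = 0.0
    if np.any(x < lo) or (not allow_zero and np.any(x == 0.0)):
        raise ValueError("x must be nonnegative" if allow_zero else "x must be positive")
    return x


def cdf(x, params) -> np.ndarray | float:
    """CBellW cumulative distribution function."""
    p = _as_params(params)
    x = _check_x(x)
    a = _kernel_a(x, p)
    b = p.a_max
    if b < _EXP_SAFE:
        out = np.expm1(a) / math.expm1(b)
    else:
        # log-space ratio: log F = logexpm1(A) - logexpm1(B)
        with np.errstate(divide="ignore"):
            out = np.exp(_log_expm1(a) - _log_expm1(b))
        out = np.where(a == 0.0, 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def survival(x, params) -> np.ndarray | float:
    """Survival function S(x) = 1 - F(x), computed without cancellation."""
    p = _as_params(params)
    x = _check_x(x)
    a = _kernel_a(x, p)
    b = p.a_max
    # S = (1 - e**(A-B)) / (1 - e**(-B)) and A <= B, so both expm1 calls
    # live on the stable negative axis
    out = np.expm1(a - b) / math.expm1(-b)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def log_pdf(x, params) -> np.ndarray | float:
    """Natural log of the CBellW density; finite wherever the density is."""
    p = _as_params(params)
    x = _check_x(x, allow_zero=False)
    g = -np.expm1(-((x / p.alpha) ** p.beta))
    a = np.expm1(p.lam * g)
    out = (
        math.log(p.lam)
        + _weibull_log_g(x, p.alpha, p.beta)
        + p.lam * g
        + a
        - float(_log_expm1(p.a_max))
    )
    return out if np.ndim(out) else float(out)


def pdf(x, params) -> np.ndarray | float:
    """CBellW probability density function."""
    out = np.exp(log_pdf(x, params))
    return out if np.ndim(out) else float(out)


def hazard(x, params) -> np.ndarray | float:
    """Hazard rate f(x)/S(x); returns inf where S underflows to zero."""
    p = _as_params(params)
    x = _check_x(x, allow_zero=False)
    s = np.asarray(survival(x, p), dtype=float)
    lf = np.asarray(log_pdf(x, p), dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(s > 0.0, np.exp(lf - np.log(np.where(s > 0, s, 1.0))), np.inf)
    return out if out.ndim else float(out)


def quantile(u, params) -> np.ndarray | float:
    """Closed-form quantile function Q(u), u in [0, 1).

    The inner term ``log(1 + u*(exp(e**lam - 1) - 1))`` is rearranged as
    ``log(u) + B + log1p(exp(-B)*(1-u)/u)`` when ``B = e**lam - 1`` is too
    large for direct evaluation.
    """
    p = _as_params(params)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u >= 1.0)):
        raise ValueError("u must lie in [0, 1)")
    b = p.a_max
    pos = u > 0.0
    usafe = np.where(pos, u, 0.5)
    if b < _EXP_SAFE:
        l1 = np.log1p(usafe * math.expm1(b))
    else:
        l1 = np.log(usafe) + b + np.log1p(np.exp(-b) * (1.0 - usafe) / usafe)
    y = np.log1p(l1) / p.lam
    # y < 1 strictly for u < 1, but rounding can push it onto 1 when u is
    # within machine epsilon of 1; saturate instead of returning infinity
    y = np.minimum(y, np.nextafter(1.0, 0.0))
    w = -np.log1p(-y)
    out = np.where(pos, p.alpha * w ** (1.0 / p.beta), 0.0)
    return out if out.ndim else float(out)


def rvs(n: int, params, seed: int) -> np.ndarray:
    """Draw ``n`` variates by inverse-transform sampling.

    The seed is mandatory: reproducibility is part of the contract.  Uses
    numpy's PCG64 generator.
    """
    p = _as_params(params)
    if not isinstance(n, (int, np.integer)) or n <= 0:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.Generator(np.random.PCG64(seed))
    u = rng.random(n)
    return np.asarray(quantile(u, p), dtype=float)
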