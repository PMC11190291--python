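"""Actuarial tail-risk measures for the CBellW loss model.

Value at Risk is the closed-form quantile; Expected Shortfall averages
VaR over levels below q; Tail Value at Risk is the conditional mean
beyond VaR, Tail Variance the conditional variance beyond it, and the
Tail Variance Premium adds a delta-loading on TV.  Quadrature over the
quantile scale is the authoritative computation (it stays stable at the
large Bell parameters fitted to heavy-tailed claims data); the
Weibull-kernel series versions of TVaR and the second tail moment are
retained for cross-checks at small lam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import mpmath as mp
import numpy as np
import pandas as pd
from scipy import integrate

from .distribution import CBellWParams, _as_params, quantile
from .series import SERIES_LAM_MAX, _property_expansion

__all__ = [
    "RiskProfile",
    "value_at_risk",
    "expected_shortfall",
    "tail_value_at_risk",
    "tail_variance",
    "tail_variance_premium",
    "risk_profile",
]


def _check_level(q: float) -> float:
    q = float(q)
    if not 0.0 < q < 1.0:
        raise ValueError("confidence level q must lie strictly between 0 and 1")
    return q


def value_at_risk(q: float, params) -> float:
    """VaR_q: the q-quantile of the loss distribution."""
    return float(quantile(_check_level(q), _as_params(params)))


def expected_shortfall(q: float, params) -> float:
    """ES_q = (1/q) * int_0^q VaR_u du (the average quantile below q)."""
    q = _check_level(q)
    p = _as_params(params)
    val, _ = integrate.quad(lambda u: quantile(u, p), 0.0, q,
                            epsrel=1e-10, limit=200)
    return float(val / q)


def _tail_quantile_integral(q: float, p: CBellWParams, power: int) -> float:
    """int_q^1 VaR_u**power du, substituting away the endpoint singularity."""
    val, _ = integrate.quad(lambda u: quantile(u, p) ** power, q, 1.0,
                            epsrel=1e-10, limit=400, points=[q, 1.0 - 1e-12])
    return float(val)


def tail_value_at_risk(q: float, params, method: str = "quadrature") -> float:
    """TVaR_q = E[X | X > VaR_q], by quadrature of the quantile function
    (or the Weibull-kernel series for small lam with ``method='series'``)."""
    q = _check_level(q)
    p = _as_params(params)
    if method == "series":
        return _tail_moment_series(q, p, r=1)
    return _tail_quantile_integral(q, p, 1) / (1.0 - q)


def _tail_moment_series(q: float, p: CBellWParams, r: int) -> float:
    """E[X**r | X > VaR_q] via the series over upper incomplete gammas."""
    if p.lam > SERIES_LAM_MAX:
        raise ValueError(
            f"series tail moments are unreliable for lam > {SERIES_LAM_MAX}; "
            "use quadrature"
        )
    ex = _property_expansion(p)
    var_q = value_at_risk(q, p)
    z0 = (var_q / p.alpha) ** p.beta
    with mp.workdps(ex._dps):
        a = mp.mpf(r) / p.beta + 1
        val = mp.fsum(
            t / mp.mpf(n + 1) ** a * mp.gammainc(a, (n + 1) * mp.mpf(z0), mp.inf)
            for n, t in enumerate(ex._t_mp)
        )
        out = mp.mpf(p.alpha) ** r * val / (1 - mp.mpf(q))
    return float(out)


def tail_variance(q: float, params, method: str = "quadrature") -> float:
    """TV_q = E[X**2 | X > VaR_q] - TVaR_q**2."""
    q = _check_level(q)
    p = _as_params(params)
    if method == "series":
        second = _tail_moment_series(q, p, r=2)
        tvar = _tail_moment_series(q, p, r=1)
    else:
        second = _tail_quantile_integral(q, p, 2) / (1.0 - q)
        tvar = tail_value_at_risk(q, p)
    return float(second - tvar**2)


def tail_variance_premium(q: float, delta: float, params) -> float:
    """TVP_q = TVaR_q + delta * TV_q, with loading delta in (0, 1)."""
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie strictly between 0 and 1")
    return tail_value_at_risk(q, params) + delta * tail_variance(q, params)


@dataclass(frozen=True)
class RiskProfile:
    """VaR/ES/TVaR/TV/TVP evaluated on a grid of confidence levels."""

    levels: np.ndarray = field(repr=False)
    var: np.ndarray = field(repr=False)
    es: np.ndarray = field(repr=False)
    tvar: np.ndarray = field(repr=False)
    tv: np.ndarray = field(repr=False)
    tvp: np.ndarray = field(repr=False)
    delta: float = 0.5
    params: CBellWParams | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.levels, "var": self.var, "es": self.es,
             "tvar": self.tvar, "tv": self.tv, "tvp": self.tvp}
        )


def risk_profile(levels, params, delta: float = 0.5) -> RiskProfile:
    """Evaluate all five measures on a grid of confidence levels."""
    p = _as_params(params)
    levels = np.asarray(levels, dtype=float)
    var = np.array([value_at_risk(q, p) for q in levels])
    es = np.array([expected_shortfall(q, p) for q in levels])
    tvar = np.array([tail_value_at_risk(q, p) for q in levels])
    tv = np.array([tail_variance(q, p) for q in levels])
    tvp = tvar + delta * tv
    return RiskProfile(levels=levels, var=var, es=es, tvar=tvar, tv=tv,
                       tvp=tvp, delta=delta, params=p)
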