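"""Model-selection criteria and goodness-of-fit statistics.

Implements the four information criteria (AIC, CAIC, BIC, HQIC), the
classical one-sample Kolmogorov-Smirnov, Anderson-Darling and
Cramer-von Mises statistics against an arbitrary fitted cdf, and the
plot-ready scaled TTT transform and P-P coordinates.

The KS p-value uses the asymptotic Kolmogorov law without a correction
for estimated parameters, and A/W are the unmodified classical forms:
both conventions match the magnitudes the method's reference tables
print.  All u-values are clipped away from {0, 1} before logarithms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import special as sp

__all__ = [
    "GofSummary",
    "information_criteria",
    "ks_statistic",
    "ad_statistic",
    "cvm_statistic",
    "gof_summary",
    "ttt_transform",
    "pp_points",
]

_CLIP = 1e-12


@dataclass(frozen=True)
class GofSummary:
    """Fit-quality summary for one model on one sample."""

    neg_loglik: float
    aic: float
    caic: float
    bic: float
    hqic: float
    ad_stat: float
    cvm_stat: float
    ks_stat: float
    ks_pvalue: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return {f: float(getattr(self, f)) if f not in ("n", "k") else getattr(self, f)
                for f in self.__dataclass_fields__}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def information_criteria(neg_loglik: float, k: int, n: int) -> tuple[float, float, float, float]:
    """(AIC, CAIC, BIC, HQIC) from the negative log-likelihood.

    AIC  = 2k + 2*nll
    CAIC = AIC + 2k(k+1)/(n-k-1)
    BIC  = 2*nll + k*log(n)
    HQIC = 2*nll + 2k*log(log(n))
    """
    if n <= k + 1:
        raise ValueError(f"CAIC undefined: need n > k+1, got n={n}, k={k}")
    aic = 2 * k + 2 * neg_loglik
    caic = aic + 2 * k * (k + 1) / (n - k - 1)
    bic = 2 * neg_loglik + k * np.log(n)
    hqic = 2 * neg_loglik + 2 * k * np.log(np.log(n))
    return float(aic), float(caic), float(bic), float(hqic)


def _probabilities(data, cdf_callable) -> np.ndarray:
    x = np.sort(np.asarray(data, dtype=float), kind="stable")
    if x.size < 2:
        raise ValueError("need at least two observations")
    u = np.asarray(cdf_callable(x), dtype=float)
    if np.any((u < -1e-9) | (u > 1 + 1e-9)):
        import warnings

        warnings.warn("cdf values outside [0,1] clipped")
    return np.clip(u, _CLIP, 1.0 - _CLIP)


def ks_statistic(data, cdf_callable) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    u = _probabilities(data, cdf_callable)
    n = u.size
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    pvalue = float(sp.kolmogorov(np.sqrt(n) * d))
    return d, pvalue


def ad_statistic(data, cdf_callable, modified: bool = False) -> float:
    """Anderson-Darling statistic A**2.

    ``modified=True`` applies the small-sample adjustment for estimated
    parameters, A* = A**2 (1 + 0.75/n + 2.25/n**2), the convention of the
    widely used goodness-of-fit routines for fitted lifetime models.
    """
    u = _probabilities(data, cdf_callable)
    n = u.size
    i = np.arange(1, n + 1)
    a2 = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
    if modified:
        a2 *= 1.0 + 0.75 / n + 2.25 / n**2
    return a2


def cvm_statistic(data, cdf_callable, modified: bool = False) -> float:
    """Cramer-von Mises statistic W**2 (optionally the estimated-parameter
    adjustment W* = W**2 (1 + 0.5/n))."""
    u = _probabilities(data, cdf_callable)
    n = u.size
    i = np.arange(1, n + 1)
    w2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1 / (12 * n))
    if modified:
        w2 *= 1.0 + 0.5 / n
    return w2


def gof_summary(data, cdf_callable, neg_loglik: float, k: int) -> GofSummary:
    """Bundle criteria and EDF statistics for one fitted model."""
    x = np.asarray(data, dtype=float)
    n = int(x.size)
    aic, caic, bic, hqic = information_criteria(neg_loglik, k, n)
    ks, p = ks_statistic(x, cdf_callable)
    return GofSummary(
        neg_loglik=float(neg_loglik),
        aic=aic, caic=caic, bic=bic, hqic=hqic,
        ad_stat=ad_statistic(x, cdf_callable),
        cvm_stat=cvm_statistic(x, cdf_callable),
        ks_stat=ks, ks_pvalue=p,
        n=n, k=k,
    )


def ttt_transform(data) -> tuple[np.ndarray, np.ndarray]:
    """Scaled total-time-on-test transform.

    Returns (i/n, TTT_i) pairs for i = 0..n with
    TTT_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_j; endpoints are
    (0,0) and (1,1).  A concave curve diagnoses an increasing hazard.
    """
    x = np.sort(np.asarray(data, dtype=float), kind="stable")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    total = float(np.sum(x))
    csum = np.cumsum(x)
    i = np.arange(1, n + 1)
    ttt = (csum + (n - i) * x) / total
    return np.concatenate(([0.0], i / n)), np.concatenate(([0.0], ttt))


def pp_points(data, cdf_callable) -> tuple[np.ndarray, np.ndarray]:
    """(empirical, theoretical) probability pairs for a P-P plot."""
    x = np.sort(np.asarray(data, dtype=float), kind="stable")
    n = x.size
    emp = (np.arange(1, n + 1) - 0.5) / n
    theo = np.asarray(cdf_callable(x), dtype=float)
    return emp, theo
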