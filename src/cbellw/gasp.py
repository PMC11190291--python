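"""Group acceptance sampling plans under a truncated life test.

A lot of items whose lifetime follows the CBellW law is sentenced by
testing g groups of r items each for a fixed time t0 = a1 * m0, where m0
is the specified median life; the lot is accepted iff every group shows at
most c failures.  The distribution median m = alpha * zeta(beta, lam)
serves as the quality parameter (preferred over the mean for skewed
lifetimes), so the scale alpha cancels and only the shape pair
(beta, lam) enters the design.

The design search returns the smallest plan meeting both risks: the
probability of accepting a lot at the specified median (true/specified
median ratio r1 = 1) must not exceed the consumer's risk, while the
probability of accepting a good lot (ratio r2 > 1) must be at least
1 - producer_risk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import CBellWParams, cdf, quantile

__all__ = [
    "GaspQuery",
    "GaspDesign",
    "median_factor",
    "failure_probabilities",
    "oc_probability",
    "design",
    "design_table",
    "TABLE_GRID",
]

# slack applied to the consumer bound before taking the ceiling, so that
# exact boundary cases (log-ratio an integer) are not pushed up a group
# by floating-point noise
_BOUNDARY_SLACK = 1e-9


class InfeasibleDesignError(RuntimeError):
    """No (g, c) with c <= r satisfies both risk constraints."""


@dataclass(frozen=True)
class GaspQuery:
    """One design question for the plan search."""

    dist_beta: float
    dist_lambda: float
    consumer_risk: float
    producer_risk: float = 0.05
    r: int = 5
    a1: float = 0.5
    r2: float = 2.0
    r1: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.consumer_risk < 1 and 0 < self.producer_risk < 1):
            raise ValueError("risks must lie strictly between 0 and 1")
        if self.r < 1:
            raise ValueError("group size r must be >= 1")
        if self.r2 <= self.r1:
            raise ValueError("need r2 > r1")
        if self.r1 != 1.0:
            raise ValueError("the design equations fix r1 = 1")
        if self.dist_beta <= 0 or self.dist_lambda <= 0 or self.a1 <= 0:
            raise ValueError("shape parameters and a1 must be positive")


@dataclass(frozen=True)
class GaspDesign:
    """Minimal accepted plan for one query."""

    g: int
    c: int
    oc_value: float  # acceptance probability at producer (good-lot) quality
    p1: float
    p2: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"g": self.g, "c": self.c, "oc_value": self.oc_value,
             "p1": self.p1, "p2": self.p2}, indent=2, **kwargs)


def median_factor(dist_beta: float, dist_lambda: float) -> float:
    """Median in units of the scale parameter: zeta = Q(0.5; alpha=1)."""
    return float(quantile(0.5, CBellWParams(1.0, dist_beta, dist_lambda)))


def failure_probabilities(q: GaspQuery) -> tuple[float, float]:
    """Per-item failure probabilities before t0 at bad-lot and good-lot quality.

    p1 evaluates the unit-scale cdf at a1*zeta (lot sitting exactly at the
    specified median, r1 = 1); p2 at a1*zeta/r2 (true median r2 times the
    specification).
    """
    zeta = median_factor(q.dist_beta, q.dist_lambda)
    p = CBellWParams(1.0, q.dist_beta, q.dist_lambda)
    p1 = float(cdf(q.a1 * zeta / q.r1, p))
    p2 = float(cdf(q.a1 * zeta / q.r2, p))
    return p1, p2


def oc_probability(g: int, c: int, r: int, p: float) -> float:
    """Lot acceptance probability [P(Bin(r, p) <= c)]**g."""
    if not 0 <= c <= r:
        raise ValueError("need 0 <= c <= r")
    if g < 1:
        raise ValueError("need g >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    # log-space power of the binomial tail
    logtail = stats.binom.logcdf(c, r, p)
    return float(np.exp(g * logtail))


def design(q: GaspQuery) -> GaspDesign:
    """Smallest (g, c) plan meeting both risk constraints.

    For each acceptance number c (ascending) the consumer constraint
    [B(c; r, p1)]**g <= consumer_risk gives the minimal group count
    g_c = ceil(log(consumer_risk)/log B); the first c whose g_c also
    meets the producer constraint wins.  Because B(c; r, p1) increases
    with c, g_c is nondecreasing in c, so this is the plan with the
    fewest groups overall (ties broken toward smaller c).
    """
    p1, p2 = failure_probabilities(q)
    for c in range(q.r + 1):
        logb = stats.binom.logcdf(c, q.r, p1)
        if logb >= 0.0:  # B == 1: consumer constraint unreachable
            break
        ratio = math.log(q.consumer_risk) / logb
        g = max(1, math.ceil(ratio - _BOUNDARY_SLACK))
        oc = oc_probability(g, c, q.r, p2)
        if oc >= 1.0 - q.producer_risk:
            return GaspDesign(g=g, c=c, oc_value=oc, p1=p1, p2=p2)
    raise InfeasibleDesignError(
        f"no feasible (g, c) with c <= r={q.r} for consumer_risk="
        f"{q.consumer_risk}, producer_risk={q.producer_risk}, r2={q.r2}"
    )


# the published design grid: consumer risk x median ratio x (r, a1) cells
TABLE_GRID = {
    "consumer_risk": (0.25, 0.10, 0.05, 0.01),
    "r2": (2, 4, 6, 8),
    "r_a1": ((5, 0.5), (5, 1.0), (10, 0.5), (10, 1.0)),
}


def design_table(
    dist_beta: float,
    dist_lambda: float,
    producer_risk: float = 0.05,
    consumer_risks=TABLE_GRID["consumer_risk"],
    r2_values=TABLE_GRID["r2"],
    r_a1_pairs=TABLE_GRID["r_a1"],
):
    """Map the design search over a grid of queries.

    Returns a pandas DataFrame with one row per cell (columns
    consumer_risk, r2, r, a1, g, c, oc); infeasible cells carry NaN
    rather than aborting the sweep.
    """
    import pandas as pd

    rows = []
    for cr in consumer_risks:
        for r2 in r2_values:
            for r, a1 in r_a1_pairs:
                q = GaspQuery(
                    dist_beta=dist_beta, dist_lambda=dist_lambda,
                    consumer_risk=cr, producer_risk=producer_risk,
                    r=r, a1=a1, r2=r2,
                )
                try:
                    d = design(q)
                    rows.append({"consumer_risk": cr, "r2": r2, "r": r, "a1": a1,
                                 "g": d.g, "c": d.c, "oc": d.oc_value})
                except InfeasibleDesignError:
                    rows.append({"consumer_risk": cr, "r2": r2, "r": r, "a1": a1,
                                 "g": np.nan, "c": np.nan, "oc": np.nan})
    return pd.DataFrame(rows)
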