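"""Maximum-likelihood fitting of the CBellW model and its comparators.

Fits are complete-sample (no censoring).  Optimisation runs in
log-parameter space — unconstrained quasi-Newton with positivity enforced
by construction — from a moment-flavoured starting point (a Weibull fit of
the data, unit Bell parameter) plus randomised restarts.  Standard errors
come from the inverse observed information, i.e. the finite-difference
Hessian of the negative log-likelihood in the natural parameterisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import distribution as dist
from .distribution import CBellWParams, _as_params

__all__ = [
    "FitResult",
    "neg_log_likelihood",
    "score",
    "fit_mle",
    "MODELS",
]


class FitError(RuntimeError):
    """All optimisation starts failed."""


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one complete sample."""

    model: str
    params: np.ndarray = field(repr=False)
    param_names: tuple[str, ...]
    se: np.ndarray | None
    neg_loglik: float
    n: int
    converged: bool
    n_starts_used: int
    gradient_norm: float

    @property
    def k(self) -> int:
        return len(self.params)

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params_dict(),
            "se": None if self.se is None else dict(zip(self.param_names, map(float, self.se))),
            "neg_loglik": float(self.neg_loglik),
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "gradient_norm": float(self.gradient_norm),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _check_data(data) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("data must be strictly positive and finite")
    return x


# --------------------------------------------------------------------------
# CBellW likelihood and score


def neg_log_likelihood(data, params) -> float:
    """Negative log-likelihood of the CBellW model for a complete sample."""
    x = _check_data(data)
    p = _as_params(params)
    return -float(np.sum(dist.log_pdf(x, p)))


def score(data, params) -> np.ndarray:
    """Score vector (dL/d alpha, dL/d beta, dL/d lam) of the log-likelihood L."""
    x = _check_data(data)
    p = _as_params(params)
    n = x.size
    a, b, lam = p.alpha, p.beta, p.lam
    z = (x / a) ** b  # (x_i/alpha)**beta
    e = np.exp(-z)
    g = -np.expm1(-z)  # 1 - exp(-z)
    w = np.exp(lam * g)  # e**(lam*G)
    logxa = np.log(x / a)
    # d/d lam
    elam = math.exp(lam)
    # e**lam * exp(e**lam - 1) / (exp(e**lam - 1) - 1), stable for large lam
    bmax = math.expm1(lam)
    ratio = elam / (-math.expm1(-bmax))
    u_lam = n / lam + np.sum(g) + np.sum(w * g) - n * ratio
    # d/d alpha
    u_alpha = (
        -n * b / a
        + (b / a) * np.sum(z)
        - (lam * b / a) * np.sum(e * z)
        - (lam * b / a) * np.sum(z * np.exp(lam * g - z))
    )
    # d/d beta
    u_beta = (
        n / b
        + np.sum(logxa)
        - np.sum(z * logxa)
        + lam * np.sum(e * z * logxa)
        + lam * np.sum(z * logxa * np.exp(lam * g - z))
    )
    return np.array([u_alpha, u_beta, u_lam])


# --------------------------------------------------------------------------
# model registry: each model exposes cdf / log_pdf / k / start values


class _CBellWModel:
    name = "cbellw"
    param_names = ("alpha", "beta", "lam")

    @staticmethod
    def cdf(x, theta):
        return dist.cdf(x, CBellWParams(*theta))

    @staticmethod
    def log_pdf(x, theta):
        return dist.log_pdf(x, CBellWParams(*theta))

    @staticmethod
    def start(x):
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        return np.array([scale, c, 1.0])

    @staticmethod
    def score(x, theta):
        return score(x, CBellWParams(*theta))


class _WeibullModel:
    """Baseline Weibull in the scale/shape form G(x) = 1 - exp(-(x/alpha)**beta)."""

    name = "weibull"
    param_names = ("alpha", "beta")

    @staticmethod
    def cdf(x, theta):
        a, b = theta
        return -np.expm1(-((np.asarray(x, dtype=float) / a) ** b))

    @staticmethod
    def log_pdf(x, theta):
        a, b = theta
        x = np.asarray(x, dtype=float)
        z = (x / a) ** b
        return math.log(b) - b * math.log(a) + (b - 1.0) * np.log(x) - z

    @staticmethod
    def start(x):
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        return np.array([scale, c])

    score = None


class _EEModel:
    """Exponentiated exponential: cdf (1 - e**(-alpha*x))**beta (alpha a rate)."""

    name = "ee"
    param_names = ("alpha", "beta")

    @staticmethod
    def cdf(x, theta):
        a, b = theta
        return (-np.expm1(-a * np.asarray(x, dtype=float))) ** b

    @staticmethod
    def log_pdf(x, theta):
        a, b = theta
        x = np.asarray(x, dtype=float)
        return (
            math.log(a)
            + math.log(b)
            - a * x
            + (b - 1.0) * np.log(-np.expm1(-a * x))
        )

    @staticmethod
    def start(x):
        return np.array([1.0 / np.mean(x), 1.0])

    score = None


class _CPWModel:
    """Complementary Poisson Weibull: the Poisson-compounded analogue,
    cdf (e**(lam*G) - 1)/(e**lam - 1) over the Weibull baseline."""

    name = "cpw"
    param_names = ("alpha", "beta", "lam")

    @staticmethod
    def cdf(x, theta):
        a, b, lam = theta
        g = -np.expm1(-((np.asarray(x, dtype=float) / a) ** b))
        return np.expm1(lam * g) / math.expm1(lam)

    @staticmethod
    def log_pdf(x, theta):
        a, b, lam = theta
        x = np.asarray(x, dtype=float)
        z = (x / a) ** b
        g = -np.expm1(-z)
        log_gpdf = math.log(b) - b * math.log(a) + (b - 1.0) * np.log(x) - z
        # log(e**lam - 1) = lam + log1p(-e**(-lam)), stable for large lam
        log_norm = lam + math.log1p(-math.exp(-lam))
        return math.log(lam) + log_gpdf + lam * g - log_norm

    @staticmethod
    def start(x):
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        return np.array([scale, c, 1.0])

    score = None


MODELS = {m.name: m for m in (_CBellWModel, _WeibullModel, _EEModel, _CPWModel)}


# --------------------------------------------------------------------------
# fitting


def _model_nll(model, x, theta) -> float:
    try:
        with np.errstate(all="ignore"):
            lp = model.log_pdf(x, theta)
    except (OverflowError, ValueError):
        return np.inf
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        return np.inf
    return -float(np.sum(lp))


def _fd_hessian(fun, theta, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1e-8)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit_mle(
    data,
    model: str = "cbellw",
    n_starts: int = 6,
    seed: int = 0,
) -> FitResult:
    """Fit a model by multi-start maximum likelihood.

    Optimises in log-parameter space with BFGS (analytic gradient for the
    CBellW model, numerical otherwise) and keeps the best of ``n_starts``
    converged runs.  Standard errors are the square roots of the diagonal
    of the inverse observed information; they are reported as None when
    the Hessian is not positive definite.
    """
    x = _check_data(data)
    if model not in MODELS:
        raise KeyError(f"unknown model {model!r}; available: {tuple(MODELS)}")
    mdl = MODELS[model]
    if x.size < 10:
        import warnings

        warnings.warn(f"sample size {x.size} < 10: MLEs may be unstable")

    def nll_log(log_theta):
        return _model_nll(mdl, x, np.exp(log_theta))

    if mdl.score is not None:

        def grad_log(log_theta):
            with np.errstate(all="ignore"):
                theta = np.exp(log_theta)
                g = -mdl.score(x, theta) * theta  # chain rule d/d log
            if not np.all(np.isfinite(g)):
                return np.full_like(theta, np.nan)
            return g

    else:
        grad_log = None

    rng = np.random.Generator(np.random.PCG64(seed))
    try:
        base = np.log(mdl.start(x))
    except Exception:
        base = np.zeros(len(mdl.param_names))
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.normal(scale=0.5, size=base.size))

    best = None
    used = 0
    for s in starts:
        used += 1
        try:
            res = optimize.minimize(nll_log, s, jac=grad_log, method="BFGS",
                                    options={"maxiter": 500, "gtol": 1e-8})
        except Exception:
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {used} optimisation starts failed for model {model!r}")

    theta = np.exp(best.x)
    nll = float(best.fun)
    # gradient norm in natural parameters
    if mdl.score is not None:
        gnorm = float(np.linalg.norm(mdl.score(x, theta)))
    else:
        gnorm = float(np.linalg.norm(
            optimize.approx_fprime(theta, lambda th: _model_nll(mdl, x, th), 1e-6 * theta)
        ))

    se = None
    try:
        hess = _fd_hessian(lambda th: _model_nll(mdl, x, th), theta)
        eigvals = np.linalg.eigvalsh(hess)
        if np.all(eigvals > 0):
            se = np.sqrt(np.diag(np.linalg.inv(hess)))
    except Exception:
        se = None

    return FitResult(
        model=model,
        params=theta,
        param_names=mdl.param_names,
        se=se,
        neg_loglik=nll,
        n=int(x.size),
        converged=bool(best.success or gnorm < 1e-2),
        n_starts_used=used,
        gradient_norm=gnorm,
    )
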