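# Methods

## Model

The complementary Bell Weibull (CBellW) law describes the lifetime of a
parallel system with a random number N of components: each component
lifetime is Weibull(α, β), N follows a zero-truncated Bell distribution
with parameter λ, and the system fails when the last component does
(X = max of the N lifetimes).  This gives

    F(x) = [exp(e^{λG(x)} − 1) − 1] / [exp(e^λ − 1) − 1],
    G(x) = 1 − exp(−(x/α)^β).

α is a scale in the units of the data; β controls early-vs-late hazard
shape; λ controls the effective number of latent risks (as λ → 0 the
truncated Bell count concentrates on 1 and the law collapses onto the
Weibull baseline — the package tests this limit).  The hazard can be
increasing, decreasing, or unimodal; the closed-form quantile

    Q(u) = α · ( −log[1 − log(1 + log(1 + u(exp(e^λ−1) − 1)))/λ] )^{1/β}

drives sampling, plan design, and the risk measures.

## Numerical design

**Log-space evaluation.**  The normalising constant involves
exp(e^λ − 1), which overflows double precision already at λ ≈ 6.6 — and
λ ≈ 6.3 occurs in the insurance-claims fit.  All ratios of the form
(e^A − 1)/(e^B − 1) are therefore computed through `expm1`/`log1p`
primitives, with the asymptotic branch `log F = A − B + log1p(−e^{−A}) −
log1p(−e^{−B})` once B exceeds 690.  The survival function uses
`expm1(A−B)/expm1(−B)`, which is cancellation-free on the whole
parameter range.  The quantile's inner term `log(1 + u(exp(e^λ−1)−1))`
is rearranged as `log u + B + log1p(e^{−B}(1−u)/u)` for large B, and the
final logarithm is saturated one ulp below 1 so that levels within
machine epsilon of 1 return a large finite quantile rather than
infinity.  The implementation agrees with a 200-digit direct
transcription of the closed forms to 1e−10 relative over the tested
parameter box (λ up to 10).

**Series expansion.**  The density expands over Weibull kernels with
coefficients ζ_v = λ^{v+1} B_{v+1} / [(v+1)! (exp(e^λ−1)−1)] and
t_n = Σ_v ζ_v (v+1)(−1)^n C(v,n).  Two facts shape the implementation:

1. the ζ series peaks near v ≈ λe^λ, so the default 200-term cap
   converges (tail < 1e−10) only up to λ ≈ 3.2; λ = 4 needs ≈ 540 terms.
   The truncation order is chosen adaptively against the dropped-mass
   bound; an unreached tolerance is reported in `tail_estimate`, never
   hidden.  Property computations (moments, tail moments) use an
   internal 700-term cap for λ ≤ 4 and adaptive quadrature beyond
   (`SERIES_LAM_MAX = 4`), where quadrature is authoritative.
2. the alternating binomial rearrangement makes individual t_n of order
   C(V, V/2) while their sums stay O(1): float64 storage destroys the
   cancellation structure.  All t_n sums are accumulated in mpmath
   extended precision (working digits ≈ 30 + 0.32·V), and the truncated
   pdf is evaluated through the algebraically identical factorisation
   g(x) Σ_v ζ_v (v+1) G(x)^v, which is positive-term and stable.

The stress–strength double series uses the exact inner alternating sum
Σ_z (−1)^z C(m,z)/(z+1), evaluated in integer arithmetic via the
identity with C(m+1, z+1) (it telescopes to 1/(m+1)).  Residual and
reversed-residual life moments go through the exact binomial identity
over (in)complete moments rather than the expansion printed in the
source, whose displayed form conflates the summation index with the
moment order.  Entropies (Rényi, Havrda–Charvat, Arimoto, Tsallis) are
all transforms of the single integral J(δ) = ∫ f^δ dx, computed by
adaptive quadrature with quantile break-points; the published series
form for them carries a dangling summation index and irregular table
values, so it is not used.

**Quadrature.**  Improper integrals over the support are split at the
1−1e−10 quantile with interior break-points at the quartiles, keeping
scipy's QUADPACK on smooth finite panels plus a small far-tail panel.

## Inference

The log-likelihood and the analytic score vector (∂L/∂α, ∂L/∂β, ∂L/∂λ)
are evaluated through the stable log-pdf.  Optimisation runs in
log-parameter space (positivity by construction) with BFGS, starting
from a Weibull fit of the data with λ = 1 plus seeded random restarts
(default 6).  Standard errors are square roots of the diagonal of the
inverse observed information — a central finite-difference Hessian of
the negative log-likelihood in the *natural* parameterisation, matching
the convention of the reference tables; they are withheld when the
Hessian is not positive definite.  Whether the reference used observed
or expected information is unstated, hence the looser (10%) SE
tolerance in the tests.

Comparator models use their standard forms: Weibull in the scale/shape
parameterisation; exponentiated exponential cdf (1 − e^{−αx})^β with α
a rate; complementary Poisson Weibull (e^{λG} − 1)/(e^λ − 1).  The
reference's "LL" column is the negative log-likelihood (its AIC values
satisfy AIC = 2k + 2·LL exactly), and this package reports `neg_loglik`
accordingly.

Known discrepancies found while validating (all reproducible from the
test suite):

- the published bone-cancer (Data-4) estimates are not a stationary
  point of the likelihood (score norm ≈ 10 there); refinement started at
  those values descends to (0.00240, 0.2416, 3.288), nll 142.596 <
  142.831.  The package reports the converged optimum and its tests
  assert the dominance rather than the published row.
- the published CPW fit for the COVID-19 data is likewise dominated
  (our optimum nll 345.878 < printed 346.593), and its printed
  parameters reproduce neither value under the standard
  parameterisations; only the never-worse property is asserted.
- the published EE AIC for the COVID-19 data is inconsistent with its
  own printed likelihood; the likelihood (which we reproduce to 3 dp)
  is asserted instead.  Computed correctly, the two-parameter EE in
  fact attains the lowest AIC on that data set, so the "best model
  everywhere" ordering is checked against the Weibull and CPW rivals
  only.

## Goodness of fit

AIC/CAIC/BIC/HQIC use the standard formulas; KS is the one-sample
statistic over order statistics with the asymptotic Kolmogorov p-value
and *no* estimated-parameter correction — the naive law reproduces the
reference p-values (e.g. 0.8511 at D = 0.0646, n = 89), a bootstrap
correction would not.  Anderson–Darling and Cramér–von Mises are
provided in both the classical forms (default) and the
estimated-parameter-adjusted forms A* = A²(1 + 0.75/n + 2.25/n²),
W* = W²(1 + 0.5/n).  Empirically the reference tables print the
adjusted statistics (the COVID-19 row matches A* to four decimals), so
the table-comparison tests use `modified=True`; the bone-cancer A/W row
matches neither convention at either the printed or the refit estimates
and is excluded from comparisons.  The scaled TTT transform of a
constant sample is identically 1 (all test time accrues at once); the
diagonal arises for exponential data.

## Sampling plans

The design uses the median m = αζ as quality parameter, with
ζ = Q(0.5; α=1) ≈ 4.5663 at the Guinea-pig shape estimates
(β = 0.7330, λ = 2.0201); α cancels from the design equations, so the
API takes shape parameters only.  Failure probabilities p1 (lot at the
specified median, ratio r1 = 1) and p2 (good lot, ratio r2) evaluate the
unit-scale cdf at a1ζ and a1ζ/r2.  The search ascends the acceptance
number c; for each c the consumer constraint gives the minimal group
count g_c = ceil(log(consumer risk)/log B(c; r, p1)), and the first c
whose plan also meets the producer constraint wins.  Since B(c; r, p1)
grows with c, g_c is nondecreasing in c, so the result minimises g with
ties broken toward smaller c — confirmed cell-by-cell by an exhaustive
(g ≤ 1000, c ≤ r) scan in the tests.  The producer's risk is 0.05 by
default (unstated in the reference; 0.05 reproduces its designs
(90, 2), (12, 2), (1, 1), while 0.10 would not).  A 1e−9 slack guards
exact-boundary cells before the ceiling: at (r = 5, a1 = 1, r2 = 2) the
log-ratio is exactly 2 (p1 = 1/2 because the test truncates at the
specified median itself), and the search returns g = 2 where the
reference prints 3.  The reference cell (r = 10, a1 = 1, r2 = 2) prints
(g = 3, c = 1, OC 0.9738) but our search returns (g = 1, c = 3) with
OC 0.973874 — matching the printed OC to four decimals, so that cell is
evidently a g/c transposition in print.

## Risk measures

VaR is the closed-form quantile; ES averages the quantile over [0, q];
TVaR and the second tail moment integrate the quantile over [q, 1]
(bounded domain, singular only in the last ulp, handled by the
saturated quantile); TV = E[X²|X>VaR] − TVaR² and TVP = TVaR + δ·TV.
Quadrature is the authoritative route because the claims fit has
λ = 6.271, far beyond the series' comfort zone; the series versions are
retained as cross-checks for λ ≤ 4 and agree to 1e−8.  The 2% test
tolerance on the claims VaR/ES reflects input rounding: the reference
prints the fitted parameters to 3 decimals, and VaR(0.55) moves by
about 1% across that rounding interval.

## Estimator study

The bias/MSE study draws each replicate and its optimiser restarts from
independent child seeds of one root seed (numpy SeedSequence), so the
whole study is a pure function of (truth, grid, reps, seed).  Failed
fits are dropped and counted; more than 20% failures at any sample size
aborts the study (none occur at the tested scales).  At 500
replications over n ∈ {50, 100, 200, 400} the MSE of every parameter
falls strictly monotonically for both truth sets (α=2, β=6, λ=0.7) and
(α=2, β=5, λ=1.2).  The reference's per-cell bias values (~0.002 at
n = 300) are far below the genuine O(1/n) bias of these MLEs (we
measure bias(β̂) ≈ 0.11 at n = 300, i.e. 1.8% of β = 6, stable across
seeds); its replication protocol is ambiguous, so the study validates
trends and the variance decomposition MSE ≥ bias², not table cells.

## Data sets

The five bundled samples are complete (uncensored) positive lifetimes;
each load re-verifies n and the sample mean against the published
descriptives, so a corrupted transcription cannot silently propagate.
The published median of the Guinea-pig data is stated as 1.51 in prose
and 1.50 in the descriptive table; the transcribed sample gives 1.495,
matching the table at printed precision.  Quartiles/sd/skewness/
kurtosis are convention-dependent (we use type-7 quantiles, biased
moment estimators, raw — not excess — kurtosis) and carry 2%
tolerances.  The UK collision-claims sample is not bundled (external
package provenance); the risk demonstrations run from the published
fitted parameters instead.

## Synthetic data and what the tests show

Synthetic fixtures come from inverse-transform sampling of the model
itself, so estimator-study and recovery tests exercise the estimator
under a correctly specified model with i.i.d. complete observations.
They do not probe censoring, covariates, model misspecification, or
rounding/ties as they occur in real registries — conclusions about
those belong to the real-data fits, which the package reproduces from
its bundled transcriptions.

## Limitations

- Complete samples only; no censored likelihood.
- The mgf is numerical quadrature only (finite for β > 1 or t ≤ 0).
- The series route degrades beyond λ = 4 by design; quadrature takes
  over silently but `expansion()` under the default cap reports an
  honest `tail_estimate` rather than failing.
- Comparator models are limited to Weibull, EE, and CPW.
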