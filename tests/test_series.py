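"""Series expansion and distributional properties against independent
quadrature / enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad

from cbellw.distribution import CBellWParams, cdf, pdf, quantile, survival
from cbellw import series as ser


def dobinski_bell(n, terms=400):
    """Independent Bell-number oracle: truncated Dobinski sum (exact
    rational arithmetic, rounded)."""
    acc = Fraction(0)
    kfact = 1
    for k in range(terms):
        if k > 0:
            kfact *= k
        acc += Fraction(k**n, kfact)
    # acc ~ e * B_n; divide by the same truncation of e
    e_acc = Fraction(0)
    kfact = 1
    for k in range(terms):
        if k > 0:
            kfact *= k
        e_acc += Fraction(1, kfact)
    return round(acc / e_acc)


def test_bell_numbers_exact_and_monotone():
    got = ser.bell_numbers(30)
    assert got[:7] == [1, 1, 2, 5, 15, 52, 203]
    assert all(got[i + 1] >= got[i] for i in range(30))
    for n in (10, 20, 30):
        assert got[n] == dobinski_bell(n)
    # arbitrary precision: B_50 has 48 digits
    assert len(str(ser.bell_numbers(50)[50])) == 48
    with pytest.raises(ValueError):
        ser.bell_numbers(-1)


@pytest.mark.parametrize("params", [(1, 1, 1), (2, 6, 0.7), (0.5, 2, 2.5)])
def test_expansion_reconstructs_pdf_and_total_mass(params):
    ex = ser.expansion(params)
    p = CBellWParams(*params)
    xs = np.asarray(quantile(np.linspace(0.05, 0.95, 15), p))
    np.testing.assert_allclose(ex.pdf(xs), np.asarray(pdf(xs, p)), atol=1e-8)
    assert ex.total_mass == pytest.approx(1.0, abs=1e-8)
    assert np.all(ex.zeta > 0)
    assert ex.tail_estimate < 1e-8


def test_expansion_reports_honest_tail_when_capped():
    """At large Bell parameter the default 200-term cap cannot converge;
    the object must say so rather than pretend."""
    ex = ser.expansion((1, 2, 4.0))  # default cap
    assert ex.tail_estimate > 1e-3
    ex_full = ser.expansion((1, 2, 4.0), max_terms=700)
    assert ex_full.tail_estimate < 1e-8


@pytest.mark.parametrize("r", [1, 2, 3, 4])
def test_series_moments_match_quadrature(r):
    p = CBellWParams(2, 6, 0.7)
    direct = quad(lambda x: x**r * pdf(x, p), 0, np.inf)[0]
    assert ser.moment(r, p) == pytest.approx(direct, rel=1e-6)


def test_moment_quadrature_route_large_lambda():
    p = CBellWParams(0.042, 0.521, 6.271)
    m1 = ser.moment(1, p)  # auto -> quadrature beyond the series comfort zone
    mc = np.mean(np.asarray(quantile(np.random.default_rng(0).random(400_000), p)))
    assert m1 == pytest.approx(mc, rel=0.02)


def test_incomplete_moment_limits_and_variance_positive(rng):
    p = CBellWParams(2, 6, 0.7)
    full = ser.moment(1, p)
    assert ser.incomplete_moment(1, float(quantile(1 - 1e-12, p)), p) == pytest.approx(
        full, rel=1e-6
    )
    assert ser.incomplete_moment(1, 0.0, p) == 0.0
    for _ in range(50):
        q = CBellWParams(rng.uniform(0.3, 3), rng.uniform(0.5, 5), rng.uniform(0.1, 3.5))
        assert ser.moment(2, q) - ser.moment(1, q) ** 2 > 0


def test_incomplete_moment_against_quadrature():
    p = CBellWParams(1, 1, 1)
    for x in (0.5, 1.0, 2.0):
        direct = quad(lambda u: u * pdf(u, p), 0, x)[0]
        assert ser.incomplete_moment(1, x, p) == pytest.approx(direct, rel=1e-6)


def test_stress_strength_symmetric_case_is_half():
    for lam in (0.3, 1.0, 2.5):
        assert ser.stress_strength(lam, lam, 1.0, 1.3) == pytest.approx(0.5, abs=1e-6)


def test_stress_strength_against_quadrature_and_complement():
    r = ser.stress_strength(2.0, 0.5, 1.0, 1.0)
    direct = quad(
        lambda x: pdf(x, (1, 1, 2.0)) * cdf(x, (1, 1, 0.5)), 0, np.inf
    )[0]
    assert r == pytest.approx(direct, abs=1e-6)
    r_swap = ser.stress_strength(0.5, 2.0, 1.0, 1.0)
    assert r + r_swap == pytest.approx(1.0, abs=1e-6)
    # quadrature route for Bell parameters beyond the series zone
    r_big = ser.stress_strength(6.0, 5.0, 1.0, 1.0)
    direct_big = quad(
        lambda x: pdf(x, (1, 1, 6.0)) * cdf(x, (1, 1, 5.0)), 0, np.inf
    )[0]
    assert r_big == pytest.approx(direct_big, abs=1e-5)


def test_residual_life_moments_match_defining_integrals():
    p = CBellWParams(1, 1, 1)
    assert ser.residual_life_moment(1, 0.0, p) == pytest.approx(
        ser.moment(1, p), rel=1e-9
    )
    t = 1.0
    direct = quad(lambda x: (x - t) * pdf(x, p), t, np.inf)[0] / survival(t, p)
    assert ser.residual_life_moment(1, t, p) == pytest.approx(direct, rel=1e-6)
    direct2 = quad(lambda x: (x - t) ** 2 * pdf(x, p), t, np.inf)[0] / survival(t, p)
    assert ser.residual_life_moment(2, t, p) == pytest.approx(direct2, rel=1e-6)


def test_reversed_residual_life_bounded_and_matches_integral(rng):
    p = CBellWParams(1, 1, 1)
    t = 1.0
    direct = quad(lambda x: (t - x) * pdf(x, p), 0, t)[0] / cdf(t, p)
    assert ser.reversed_residual_life_moment(1, t, p) == pytest.approx(direct, rel=1e-6)
    for _ in range(10):
        tt = rng.uniform(0.2, 5)
        q = CBellWParams(rng.uniform(0.5, 2), rng.uniform(0.5, 3), rng.uniform(0.2, 3))
        assert ser.reversed_residual_life_moment(1, tt, q) <= tt
    with pytest.raises(ValueError):
        ser.reversed_residual_life_moment(1, 0.0, p)


def test_entropy_cross_identities(rng):
    """All four entropies are transforms of one integral: the identities
    linking them hold to near machine precision."""
    for _ in range(20):
        delta = float(rng.uniform(0.4, 3.0))
        if abs(delta - 1.0) < 0.05:
            delta += 0.1
        p = CBellWParams(rng.uniform(0.5, 2), rng.uniform(0.8, 4), rng.uniform(0.2, 4))
        r = ser.entropy("renyi", delta, p)
        j = math.exp((1.0 - delta) * r)
        assert ser.entropy("tsallis", delta, p) == pytest.approx(
            (1.0 - j) / (delta - 1.0), abs=1e-9
        )
        assert ser.entropy("havrda_charvat", delta, p) == pytest.approx(
            (j - 1.0) / (2.0 ** (1.0 - delta) - 1.0), abs=1e-9
        )
        assert ser.entropy("arimoto", delta, p) == pytest.approx(
            delta * (j ** (1.0 / delta) - 1.0) / (1.0 - delta), abs=1e-9
        )


def test_renyi_entropy_against_direct_quadrature():
    p = CBellWParams(1, 2, 1)
    j = quad(lambda x: pdf(x, p) ** 2, 0, np.inf)[0]
    assert ser.entropy("renyi", 2.0, p) == pytest.approx(-math.log(j), rel=1e-8)
    # order -> 1 recovers Shannon entropy
    shannon = ser.shannon_entropy(p)
    assert ser.entropy("renyi", 1.0001, p) == pytest.approx(shannon, abs=1e-2)
    with pytest.raises(ValueError):
        ser.entropy("renyi", 1.0, p)
    with pytest.raises(ValueError):
        ser.entropy("nope", 2.0, p)


def test_skewness_kurtosis_conventions():
    p = CBellWParams(2, 6, 0.7)
    b1, b2 = ser.skewness_kurtosis(p)
    s, k = ser.skewness_kurtosis(p, pearson=True)
    assert s == pytest.approx(math.copysign(math.sqrt(b1), s))
    assert k == pytest.approx(b2 - 3.0)
    # cross-check against a large seeded sample
    from cbellw.distribution import rvs
    x = rvs(400_000, p, seed=13)
    m = x.mean()
    mu2, mu3, mu4 = ((x - m) ** 2).mean(), ((x - m) ** 3).mean(), ((x - m) ** 4).mean()
    assert b1 == pytest.approx(mu3**2 / mu2**3, rel=0.05)
    assert b2 == pytest.approx(mu4 / mu2**2, rel=0.05)


def test_mgf_by_quadrature_matches_moment_expansion():
    p = CBellWParams(2, 6, 0.7)
    t = 0.1
    approx = sum(t**r / math.factorial(r) * ser.moment(r, p) for r in range(8))
    assert ser.mgf(t, p) == pytest.approx(approx, rel=1e-4)
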