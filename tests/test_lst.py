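"""LST evaluation: Taylor disc, functional-equation composition, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln

from timeshifts import (
    BranchingModel,
    LSTConfig,
    LSTEvaluator,
    MomentTable,
    error_radius,
    lst_for_initial,
    sir_analytic_lst,
)
from timeshifts.lst import embedded_pgf

from conftest import SIR_BETA, SIR_GAMMA


@pytest.fixture(scope="module")
def sir_ev(sir_pair):
    return LSTEvaluator(sir_pair[0])


@pytest.fixture(scope="module")
def seir_ev(seir_pair):
    return LSTEvaluator(seir_pair[0])


def test_lst_at_zero_is_one(sir_ev, seir_ev):
    assert np.allclose(sir_ev(np.array([0.0 + 0j])), 1.0)
    assert np.allclose(seir_ev(np.array([0.0 + 0j])), 1.0)
    assert sir_ev.kappa(0.0) == 0


def test_taylor_against_analytic_inside_disc(sir_ev):
    theta = 0.05
    exact = sir_analytic_lst(SIR_BETA, SIR_GAMMA, theta)
    assert abs(sir_ev.taylor(np.array(theta + 0j))[0] - exact) <= 1e-6


def test_taylor_first_derivative_is_minus_mean(sir_ev, seir_ev):
    for ev in (sir_ev, seir_ev):
        d = ev.taylor_deriv(np.array(0.0 + 0j))
        assert np.allclose(-d, ev.eig.u, atol=1e-14)


def test_error_radius_algebraic_identity():
    n = 4
    eps = 1e-6
    xi = np.ones((1, n + 2))
    xi[0, n + 1] = np.exp(gammaln(n + 2)) * eps  # gamma = (n+1)! eps => L = 1
    table = MomentTable(xi)
    assert error_radius(table, n, eps) == pytest.approx(1.0, rel=1e-12)


def test_error_radius_monotone_in_eps(sir_ev):
    t = sir_ev.table
    assert error_radius(t, 30, 1e-5) > error_radius(t, 30, 1e-6)


def test_lst_matches_sir_closed_form_on_complex_grid(sir_ev):
    rng = np.random.default_rng(0)
    r = rng.uniform(0.01, 100, 40)
    ang = rng.uniform(-np.pi / 2, np.pi / 2, 40)  # Re theta >= 0
    thetas = r * np.exp(1j * ang)
    got = sir_ev(thetas)[:, 0]
    exact = sir_analytic_lst(SIR_BETA, SIR_GAMMA, thetas)
    assert np.max(np.abs(got - exact)) <= 10 * sir_ev.config.eps


def test_functional_equation_residual_seir(seir_ev):
    """phi(theta) = f~(phi(theta e^{-lam h})) to 1e-8 on the test points."""
    h = seir_ev.config.h
    lam = seir_ev.eig.lam
    for theta in (1 + 0j, 10j, 20 + 20j, 50 + 0j):
        lhs = seir_ev(np.array([theta]))[0]
        inner = seir_ev(np.array([theta * np.exp(-lam * h)]))[0]
        rhs = embedded_pgf(seir_ev.model, inner, h)
        assert np.max(np.abs(lhs - rhs)) <= 1e-8


def test_fused_propagation_equals_literal_composition(seir_ev):
    """kappa h fused integration == kappa explicit embedded-pgf applications."""
    theta = 3.0 + 1.0j
    k = seir_ev.kappa(theta)
    assert k >= 1
    small = theta * np.exp(-seir_ev.eig.lam * seir_ev.config.h * k)
    start = seir_ev.taylor(np.asarray(small))
    before = seir_ev.n_embedded_applications
    literal = seir_ev.iterate_embedded(start, k)
    assert seir_ev.n_embedded_applications - before == k  # composition count
    fused = seir_ev(np.array([theta]))[0]
    assert np.max(np.abs(literal - fused)) < 1e-9


def test_embedded_pgf_properties(sir_pair, seir_pair):
    bp_seir = seir_pair[0]
    # s = 1 is a fixed point
    assert np.allclose(embedded_pgf(bp_seir, np.ones(2), 0.5), 1.0, atol=1e-10)
    # small h: f~(s) ~ s + h a (f(s) - s)
    s = np.array([0.3, 0.8], dtype=complex)
    h = 1e-4
    a = bp_seir.lifetime_rates()
    first_order = s + h * a * (bp_seir.pgf_all(s) - s)
    assert np.allclose(embedded_pgf(bp_seir, s, h), first_order, atol=1e-7)
    # SIR birth-death closed-form transient pgf
    bp_sir = sir_pair[0]
    beta, gamma = SIR_BETA, SIR_GAMMA
    lam = beta - gamma
    h = 0.1
    for s0 in (0.3 + 0j, 0.9 + 0.2j):
        e = np.exp(-lam * h)
        exact = (gamma * (s0 - 1) - e * (beta * s0 - gamma)) / (
            beta * (s0 - 1) - e * (beta * s0 - gamma)
        )
        got = embedded_pgf(bp_sir, np.array([s0]), h)[0]
        assert abs(got - exact) < 1e-9


def test_lst_magnitude_bound_on_right_half_plane(seir_ev):
    rng = np.random.default_rng(1)
    thetas = rng.uniform(0, 60, 25) + 1j * rng.uniform(-60, 60, 25)
    vals = seir_ev(thetas)
    assert np.all(np.abs(vals) <= 1 + 1e-9)


@given(re=st.floats(0.0, 50.0), im=st.floats(-50.0, 50.0))
def test_conjugate_symmetry(sir_pair, re, im):
    ev = LSTEvaluator(sir_pair[0])
    theta = complex(re, im)
    a = ev(np.array([theta]))[0, 0]
    b = ev(np.array([np.conj(theta)]))[0, 0]
    assert abs(np.conj(a) - b) < 1e-9


def test_large_theta_limit_is_extinction_probability(sir_pair, seir_pair):
    for bp, _ in (sir_pair, seir_pair):
        ev = LSTEvaluator(bp)
        q = bp.extinction_probs()
        got = ev(np.array([1e6 + 0j])).real[0]
        assert np.allclose(got, q, atol=1e-4)


def test_lst_for_initial(seir_ev):
    phis = seir_ev(np.array([1.0 + 0j]))
    assert lst_for_initial(phis, [1, 0])[0] == pytest.approx(phis[0, 0])
    assert lst_for_initial(phis, [2, 0])[0] == pytest.approx(phis[0, 0] ** 2)
    # the (E, I) = (15, 10) product stays a valid LST value
    rng = np.random.default_rng(2)
    thetas = rng.uniform(0, 30, 20) + 1j * rng.uniform(-30, 30, 20)
    prod = lst_for_initial(seir_ev(thetas), [15, 10])
    assert np.all(np.abs(prod) <= 1 + 1e-9)
    with pytest.raises(ValueError):
        lst_for_initial(phis, [1, 0, 0])


def test_discrete_lst_functional_equation():
    beta = np.zeros((1, 1, 1))
    beta[0, 0, 0] = 0.7
    gw = BranchingModel(np.array([0.3]), np.zeros((1, 1)), beta, discrete=True)
    ev = LSTEvaluator(gw, config=LSTConfig(n=30, h=1.0))
    rho = ev.eig.rho
    for theta in (0.0 + 0j, 0.5 + 0j, 2.0 + 1.0j, 10.0 + 0j):
        lhs = ev(np.array([theta]))[0]
        rhs = gw.pgf_all(ev(np.array([theta / rho]))[0])
        assert np.max(np.abs(lhs - rhs)) < 1e-8


def test_mean_from_product_lst_derivative(seir_wd):
    """-phi'(0+) = E[W] = z0 . u, via the analytic LST derivative."""
    d = seir_wd.lst_deriv(np.array([1e-9 + 0j]))[0]
    assert -d.real == pytest.approx(seir_wd.mu_w, rel=1e-6)
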