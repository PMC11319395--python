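"""Model structure, eigen-quantities and extinction probabilities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

from timeshifts import BranchingModel, SubcriticalError, eigen_quantities, fixtures
from timeshifts.lst import embedded_pgf

from conftest import SEIR_PARAMS, SIR_BETA, SIR_GAMMA, SIR_Q


def test_lifetime_rates_of_fixtures(sir_pair, seir_pair, innate_pair):
    assert np.allclose(sir_pair[0].lifetime_rates(), [SIR_BETA + SIR_GAMMA])
    assert np.allclose(seir_pair[0].lifetime_rates(), [0.5, 0.89])
    assert np.allclose(innate_pair[0].lifetime_rates(), [5.0, 48.6, 12.0])


def test_pgf_normalisation_at_one(sir_pair, seir_pair, innate_pair):
    for bp, _ in (sir_pair, seir_pair, innate_pair):
        ones = np.ones(bp.m)
        assert np.allclose(bp.pgf_all(ones), 1.0, atol=1e-14)


@given(
    nu=st.floats(0.01, 5.0),
    a12=st.floats(0.01, 5.0),
    b=st.floats(0.01, 5.0),
)
def test_pgf_normalisation_random_two_type(nu, a12, b):
    """f_i(1) = 1 holds for any nonnegative rate assignment."""
    alpha = np.array([[0.0, a12], [0.0, 0.0]])
    beta = np.zeros((2, 2, 2))
    beta[1, 0, 1] = b
    model = BranchingModel(np.array([0.0, nu]), alpha, beta)
    assert np.allclose(model.pgf_all(np.ones(2)), 1.0, atol=1e-12)


def test_pgf_values(sir_pair, seir_pair):
    # SEIR f1(s) = s2
    assert seir_pair[0].pgf(0, np.array([0.3, 0.4])) == pytest.approx(0.4)
    # SIR f(0) = gamma / (beta + gamma)
    assert sir_pair[0].pgf(0, np.array([0.0])) == pytest.approx(
        SIR_GAMMA / (SIR_BETA + SIR_GAMMA)
    )
    with pytest.raises(IndexError):
        sir_pair[0].pgf(3, np.array([0.0]))


def test_growth_matrices(sir_pair, seir_pair):
    assert np.allclose(sir_pair[0].growth_matrix(), [[SIR_BETA - SIR_GAMMA]])
    beta, sigma, gamma = SEIR_PARAMS
    assert np.allclose(
        seir_pair[0].growth_matrix(), [[-sigma, sigma], [beta, -gamma]]
    )
    # pure-death model: Omega = [-nu]
    dead = BranchingModel(np.array([1.0]), np.zeros((1, 1)), np.zeros((1, 1, 1)))
    assert np.allclose(dead.growth_matrix(), [[-1.0]])
    with pytest.raises(SubcriticalError):
        dead.eigen()


def test_eigen_quantities_sir(sir_pair):
    eig = sir_pair[0].eigen()
    assert eig.lam == pytest.approx(SIR_BETA - SIR_GAMMA)
    assert np.allclose(eig.u, [1.0]) and np.allclose(eig.v, [1.0])


def test_eigen_quantities_seir(seir_pair):
    beta, sigma, gamma = SEIR_PARAMS
    eig = seir_pair[0].eigen()
    lam_exact = (-(sigma + gamma) + np.sqrt((sigma - gamma) ** 2 + 4 * sigma * beta)) / 2
    assert eig.lam == pytest.approx(lam_exact, rel=1e-12)
    assert eig.u.sum() == pytest.approx(1.0)
    assert eig.u @ eig.v == pytest.approx(1.0)
    assert np.all(eig.u > 0) and np.all(eig.v > 0)
    O = seir_pair[0].growth_matrix()
    assert np.allclose(O @ eig.u, eig.lam * eig.u, atol=1e-12)
    assert np.allclose(eig.v @ O, eig.lam * eig.v, atol=1e-12)


def test_subcritical_raises():
    with pytest.raises(SubcriticalError):
        fixtures.sir(beta=0.4, gamma=0.5)[0].eigen()


def test_extinction_probabilities(sir_pair, seir_pair):
    bp, _ = sir_pair
    q = bp.extinction_probs()
    assert q[0] == pytest.approx(SIR_Q, abs=1e-12)
    # fixed-point residual and minimality (iterating from 1 stays at 1)
    assert abs(bp.pgf(0, q) - q[0]) < 1e-12
    ones = np.ones(1)
    for _ in range(100):
        ones = np.real(bp.pgf_all(ones))
    assert ones[0] == pytest.approx(1.0, abs=1e-12)
    # SEIR: q1 = q2 = gamma / beta analytically
    beta, sigma, gamma = SEIR_PARAMS
    q2 = seir_pair[0].extinction_probs()
    assert np.allclose(q2, gamma / beta, atol=1e-12)
    # q* for unit initial conditions picks out q_i
    assert seir_pair[0].extinction_prob_initial([1, 0]) == pytest.approx(q2[0])
    with pytest.raises(ValueError):
        seir_pair[0].extinction_prob_initial([0, 0])


def test_beta_folding_normalises_lower_triangle():
    b1 = np.zeros((2, 2, 2))
    b1[1, 0, 1] = 0.56
    b2 = np.zeros((2, 2, 2))
    b2[1, 1, 0] = 0.56  # given in the k > l order
    m1 = BranchingModel(np.array([0.0, 0.33]), np.array([[0, 0.5], [0, 0]]), b1)
    m2 = BranchingModel(np.array([0.0, 0.33]), np.array([[0, 0.5], [0, 0]]), b2)
    assert np.array_equal(m1.beta, m2.beta)


def test_discrete_probabilities_must_sum_to_one():
    beta = np.zeros((1, 1, 1))
    beta[0, 0, 0] = 0.7
    BranchingModel(np.array([0.3]), np.zeros((1, 1)), beta, discrete=True)
    with pytest.raises(ValueError):
        BranchingModel(np.array([0.5]), np.zeros((1, 1)), beta, discrete=True)


def test_reducible_model_warns():
    alpha = np.array([[0.0, 1.0], [0.0, 0.0]])  # 1 -> 2 but never back
    with pytest.warns(UserWarning, match="reducible"):
        BranchingModel(np.array([0.5, 1.0]), alpha, np.zeros((2, 2, 2)))


def test_eigen_normalisation_contract():
    mat = np.array([[-0.5, 0.5], [0.56, -0.33]])
    eig = eigen_quantities(mat)
    assert eig.u.sum() == pytest.approx(1.0)
    assert eig.u @ eig.v == pytest.approx(1.0)


def test_discrete_eigen_uses_log_rho():
    beta = np.zeros((1, 1, 1))
    beta[0, 0, 0] = 0.7
    gw = BranchingModel(np.array([0.3]), np.zeros((1, 1)), beta, discrete=True)
    eig = gw.eigen()
    assert eig.rho == pytest.approx(1.4)  # mean offspring 2 * 0.7
    assert eig.lam == pytest.approx(np.log(1.4))


def test_embedded_mean_matrix_matches_matrix_exponential(seir_pair):
    """The mean matrix of the h-step embedded process is expm(Omega h).

    Its dominant eigenvalue is therefore e^{lam h}: the discrete chain
    embedded in the continuous process grows at the same rate.
    """
    bp, _ = seir_pair
    h = 0.1
    eig = bp.eigen()
    M = np.empty((bp.m, bp.m))
    d = 1e-6
    base = np.ones(bp.m)
    for j in range(bp.m):
        up, dn = base.copy(), base.copy()
        up[j] += d
        dn[j] -= d
        M[:, j] = (embedded_pgf(bp, up, h) - embedded_pgf(bp, dn, h)).real / (2 * d)
    expected = expm(bp.growth_matrix() * h)
    assert np.allclose(M, expected, atol=1e-7)
    rho = np.max(np.linalg.eigvals(M).real)
    assert rho == pytest.approx(np.exp(eig.lam * h), rel=1e-6)
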