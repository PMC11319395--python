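"""Multitype Markov branching process models.

A continuous-time multitype Markov branching process (CT-MBP) tracks counts
``Z_i(t)`` of individuals of types ``i = 1..m``.  Each type-``i`` individual
lives an Exp(``a_i``) lifetime and on death produces offspring according to a
progeny generating function restricted to the death / linear / quadratic
family

    f_i(s) = ( nu_i + sum_{j != i} alpha_ij s_j
               + sum_{k <= l} beta_ikl s_k s_l ) / a_i,

with lifetime rate ``a_i = nu_i + sum_j alpha_ij + sum_{k<=l} beta_ikl``.
``nu_i`` is the rate of dying childless, ``alpha_ij`` the rate of turning
into one type-``j`` individual, and ``beta_ikl`` the rate of splitting into a
type-``k`` and a type-``l`` individual.  In the discrete-time variant
(DT-MBP) the same arrays hold offspring *probabilities* (summing to one per
type) and lifetimes are unit steps.

The module also provides the linear-algebra layer: the growth matrix Omega
(mean offspring matrix M in discrete time), its Perron eigen-pair with the
normalisation ``u . 1 = 1``, ``u . v = 1``, and extinction probabilities as
the minimal fixed point of the progeny generating functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import linalg


class SubcriticalError(ValueError):
    """Raised when a computation requires a supercritical process.

    The martingale-limit machinery only makes sense when the growth rate
    lambda is positive (equivalently rho > 1 in discrete time); otherwise
    extinction is certain and W degenerates at zero.
    """


@dataclass
class BranchingModel:
    """A CT- or DT-MBP with death/linear/quadratic progeny rules.

    Parameters
    ----------
    nu : (m,) array
        Death-without-offspring rates (probabilities if ``discrete``).
    alpha : (m, m) array
        ``alpha[i, j]`` is the rate of type ``i`` dying and producing one
        type ``j``.  The diagonal must be zero.
    beta : (m, m, m) array
        ``beta[i, k, l]`` is the rate of type ``i`` splitting into one
        type ``k`` plus one type ``l``.  Entries with ``k > l`` are folded
        into their ``k <= l`` mirror on construction.
    discrete : bool
        If true the entries are offspring probabilities and must sum to one
        for every type.
    """

    nu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    discrete: bool = False
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        m = self.nu.shape[0]
        self.m = m
        if self.alpha.shape != (m, m) or self.beta.shape != (m, m, m):
            raise ValueError("alpha must be (m, m) and beta (m, m, m)")
        if np.any(self.nu < 0) or np.any(self.alpha < 0) or np.any(self.beta < 0):
            raise ValueError("all rates must be nonnegative")
        if np.any(np.diag(self.alpha) != 0):
            raise ValueError("alpha diagonal must be zero (type i cannot linearly beget itself)")
        # fold lower-triangular quadratic entries into the canonical l >= k slot
        lower = np.tril(np.ones((m, m)), k=-1).astype(bool)
        folded = self.beta.copy()
        for i in range(m):
            bi = folded[i]
            folded[i] = np.triu(bi) + np.tril(bi, k=-1).T
        self.beta = folded
        assert not np.any(self.beta[:, lower])
        if self.discrete:
            tot = self.nu + self.alpha.sum(axis=1) + self.beta.sum(axis=(1, 2))
            if not np.allclose(tot, 1.0, atol=1e-10):
                raise ValueError("discrete model: offspring probabilities must sum to 1 per type")
        else:
            if np.any(self.lifetime_rates() <= 0):
                raise ValueError("every type needs a positive total event rate a_i")
        if not self.is_irreducible():
            warnings.warn(
                "mean matrix is reducible; the Perron theory assumes irreducibility",
                stacklevel=2,
            )

    # -- basic quantities -------------------------------------------------
    def lifetime_rates(self) -> np.ndarray:
        """Total event rate a_i = nu_i + sum alpha_ij + sum_{k<=l} beta_ikl."""
        if self.discrete:
            raise ValueError("lifetime rates are a continuous-time notion")
        return self.nu + self.alpha.sum(axis=1) + self.beta.sum(axis=(1, 2))

    def pgf(self, i: int, s: np.ndarray) -> complex:
        """Progeny generating function f_i evaluated at a (complex) vector s."""
        if not 0 <= i < self.m:
            raise IndexError(f"type index {i} out of range for m={self.m}")
        return self.pgf_all(np.asarray(s))[i]

    def pgf_all(self, s: np.ndarray) -> np.ndarray:
        """All f_i(s) at once; `s` may be complex, shape (m,) or (batch, m)."""
        s = np.asarray(s)
        lin = self.nu + s @ self.alpha.T
        quad = np.einsum("ikl,...k,...l->...i", self.beta, s, s)
        out = lin + quad
        if not self.discrete:
            out = out / self.lifetime_rates()
        return out

    def growth_matrix(self) -> np.ndarray:
        """Omega (continuous) or the mean offspring matrix M (discrete).

        Omega_ij = alpha_ij + sum_{k<=l} beta_ikl (delta_jk + delta_jl)
                   - a_i delta_ij;  M drops the -a_i delta_ij term and the
        discrete entries are already probabilities.
        """
        quad = self.beta.sum(axis=2) + self.beta.sum(axis=1)  # offspring counts from splits
        M = self.alpha + quad
        if self.discrete:
            return M
        return M - np.diag(self.lifetime_rates())

    def is_irreducible(self) -> bool:
        """Strong connectivity of the directed graph of possible offspring types."""
        if self.m == 1:
            return True
        quad = self.beta.sum(axis=2) + self.beta.sum(axis=1)
        pattern = (self.alpha + quad) > 0
        np.fill_diagonal(pattern, False)
        g = nx.DiGraph(pattern)
        return nx.is_strongly_connected(g)

    # -- derived structures ----------------------------------------------
    def eigen(self) -> "EigenSystem":
        return eigen_quantities(self.growth_matrix(), discrete=self.discrete)

    def extinction_probs(self, tol: float = 1e-14, max_iter: int = 10**6) -> np.ndarray:
        """Minimal nonnegative fixed point q of f(q) = q.

        Monotone fixed-point iteration from q = 0 converges to the minimal
        solution; the other root of f(q) = q is q = 1.
        """
        self.eigen()  # raises SubcriticalError if lambda <= 0
        q = np.zeros(self.m)
        for _ in range(max_iter):
            q_next = np.real(self.pgf_all(q))
            if np.max(np.abs(q_next - q)) < tol:
                return np.clip(q_next, 0.0, 1.0)
            q = q_next
        raise RuntimeError("extinction fixed-point iteration did not converge")

    def extinction_prob_initial(self, z0: np.ndarray) -> float:
        """q* = prod_i q_i^{z0_i}, the extinction probability from counts z0."""
        z0 = check_initial_condition(z0, self.m)
        return float(np.prod(self.extinction_probs() ** z0))


@dataclass
class EigenSystem:
    """Perron eigen-data of the growth matrix.

    ``lam`` is the Malthusian parameter (log of the dominant eigenvalue
    ``rho`` in discrete time); ``u`` (mean of W started from one individual
    of each type) and ``v`` (asymptotic type composition) are the right and
    left eigenvectors with ``u . 1 = 1`` and ``u . v = 1``.
    """

    growth_matrix: np.ndarray
    lam: float
    u: np.ndarray
    v: np.ndarray
    rho: float | None = None
    discrete: bool = False


def eigen_quantities(growth_matrix: np.ndarray, discrete: bool = False) -> EigenSystem:
    """Dominant eigen-pair of Omega (or M), normalised u.1 = 1, u.v = 1.

    Raises
    ------
    SubcriticalError
        If the growth rate is not positive (rho <= 1 in the discrete case).
    """
    A = np.asarray(growth_matrix, dtype=float)
    vals, vl, vr = linalg.eig(A, left=True, right=True)
    idx = int(np.argmax(vals.real))
    lead = vals[idx]
    if abs(lead.imag) > 1e-9 * max(1.0, abs(lead.real)):
        raise ValueError("dominant eigenvalue is not real; matrix is not Perron-like")
    others = np.delete(vals.real, idx)
    if others.size and np.max(others) > lead.real - 1e-12 * max(1.0, abs(lead.real)):
        raise ValueError("dominant eigenvalue is not simple")
    u = vr[:, idx].real
    v = vl[:, idx].real
    # scale to positive orientation; Perron vectors of an irreducible matrix
    # can always be chosen strictly positive
    if u.sum() < 0:
        u = -u
    if v.sum() < 0:
        v = -v
    if np.any(u <= 0) or np.any(v <= 0):
        raise ValueError("eigenvectors cannot be scaled strictly positive; not irreducible?")
    u = u / u.sum()
    v = v / (u @ v)
    if discrete:
        rho = float(lead.real)
        if rho <= 1.0:
            raise SubcriticalError(f"rho = {rho:.6g} <= 1: process is not supercritical")
        return EigenSystem(A, float(np.log(rho)), u, v, rho=rho, discrete=True)
    lam = float(lead.real)
    if lam <= 0.0:
        raise SubcriticalError(f"lambda = {lam:.6g} <= 0: process is not supercritical")
    return EigenSystem(A, lam, u, v)


def check_initial_condition(z0, m: int) -> np.ndarray:
    """Validate an initial count vector: nonnegative integers, not all zero."""
    z0 = np.asarray(z0)
    if z0.shape != (m,):
        raise ValueError(f"z0 must have length {m}")
    if np.any(z0 < 0) or np.any(z0 != np.round(z0)):
        raise ValueError("z0 must be nonnegative integers")
    if z0.sum() == 0:
        raise ValueError("z0 must contain at least one individual")
    return z0.astype(int)
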