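"""Conditional moments of the martingale limit W.

For a supercritical CT-MBP the moment generating function of W_i (the limit
started from one type-i individual) satisfies a functional equation that,
for the death/linear/quadratic progeny family, differentiates into a closed
recursion: the vector of n-th moments solves a linear system

    C^(n) Xi^(n) = d^(n),   n >= 2,

whose row i has diagonal entry 1, off-diagonal entries -alpha_ij/(a_i + n*lam)
and -(beta_ikl coefficients)/(a_i + n*lam) on the columns of the offspring
types, and whose right-hand side mixes lower-order moments through binomial
convolutions.  The first moments are Xi^(1) = u, the Perron right
eigenvector.  The discrete-time analogue follows from differentiating
Xi(theta) = f(Xi(theta / rho)) directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb, gammaln

from .branching import BranchingModel, EigenSystem, check_initial_condition


def _binom(n: int, r) -> np.ndarray:
    """Binomial coefficients; exact below n = 60, log-gamma floats above."""
    if n <= 60:
        return np.asarray(comb(n, r, exact=False))
    r = np.asarray(r, dtype=float)
    return np.exp(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1))


@dataclass
class MomentTable:
    """Moments xi[i, n] = E[W_i^n], n = 1..n_max (xi[:, 0] = 1)."""

    xi: np.ndarray  # shape (m, n_max + 1)

    @property
    def m(self) -> int:
        return self.xi.shape[0]

    @property
    def n_max(self) -> int:
        return self.xi.shape[1] - 1

    def moment(self, i: int, n: int) -> float:
        return float(self.xi[i, n])

    def to_text(self, path) -> None:
        """Write an orders-by-types delimited table for inspection."""
        header = "order\t" + "\t".join(f"E[W_{i}^n]" for i in range(self.m))
        rows = np.column_stack([np.arange(self.n_max + 1), self.xi.T])
        np.savetxt(path, rows, delimiter="\t", header=header, comments="")


def moment_recursion(model: BranchingModel, eig: EigenSystem, n_max: int) -> MomentTable:
    """Moments E[W_i^n] for n = 1..n_max of a continuous-time model."""
    if model.discrete:
        return moment_recursion_discrete(model, eig, n_max)
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    m, lam = model.m, eig.lam
    if lam <= 0:
        raise ValueError("moment recursion requires a supercritical model")
    a = model.lifetime_rates()
    xi = np.empty((m, n_max + 1))
    xi[:, 0] = 1.0
    xi[:, 1] = eig.u
    quads = [
        (i, k, l, model.beta[i, k, l])
        for i in range(m)
        for k in range(m)
        for l in range(k, m)
        if model.beta[i, k, l] > 0
    ]
    for n in range(2, n_max + 1):
        denom = a + n * lam
        C = np.eye(m) - model.alpha / denom[:, None]
        np.fill_diagonal(C, 1.0)  # alpha diagonal is zero anyway
        d = np.zeros(m)
        w = _binom(n, np.arange(1, n))
        for i, k, l, b in quads:
            bt = b / denom[i]
            C[i, k] -= bt
            C[i, l] -= bt
            d[i] += bt * np.sum(w * xi[k, 1:n] * xi[l, n - 1 : 0 : -1])
        xi[:, n] = np.linalg.solve(C, d)
    return MomentTable(xi)


def moment_recursion_discrete(model: BranchingModel, eig: EigenSystem, n_max: int) -> MomentTable:
    """Moments E[W_i^n] for a supercritical DT-MBP (rho > 1)."""
    if not model.discrete:
        raise ValueError("model is not discrete")
    if eig.rho is None or eig.rho <= 1:
        raise ValueError("discrete recursion requires rho > 1")
    m, rho = model.m, eig.rho
    xi = np.empty((m, n_max + 1))
    xi[:, 0] = 1.0
    xi[:, 1] = eig.u
    quads = [
        (i, k, l, model.beta[i, k, l])
        for i in range(m)
        for k in range(m)
        for l in range(k, m)
        if model.beta[i, k, l] > 0
    ]
    for n in range(2, n_max + 1):
        # rho^n xi_i - sum_j alpha_ij xi_j - sum beta (xi_k + xi_l) = rhs
        C = np.eye(m) * rho**n - model.alpha
        d = np.zeros(m)
        w = _binom(n, np.arange(1, n))
        for i, k, l, b in quads:
            C[i, k] -= b
            C[i, l] -= b
            d[i] += b * np.sum(w * xi[k, 1:n] * xi[l, n - 1 : 0 : -1])
        xi[:, n] = np.linalg.solve(C, d)
    return MomentTable(xi)


def w_moments_from_initial(table: MomentTable, z0, k_max: int | None = None) -> np.ndarray:
    """Moments E[W^k], k = 0..k_max, for W = sum of independent W_i copies.

    Uses the fact that for independent summands the exponential moment
    sequence E[X^k]/k! multiplies like polynomial coefficients: the k-fold
    binomial convolution of the per-copy sequences (equivalent to the
    multinomial/integer-partition expansion, without enumerating partitions).
    """
    z0 = check_initial_condition(z0, table.m)
    if k_max is None:
        k_max = table.n_max
    if k_max > table.n_max:
        raise ValueError(f"k_max = {k_max} exceeds available moment order {table.n_max}")
    kf = np.cumprod(np.concatenate(([1.0], np.arange(1, k_max + 1))))
    out = np.zeros(k_max + 1)
    out[0] = 1.0
    for i in range(table.m):
        seq = table.xi[i, : k_max + 1] / kf
        for _ in range(int(z0[i])):
            out = np.convolve(out, seq)[: k_max + 1]
    return out * kf


def w_moments_by_partitions(table: MomentTable, z0, k: int) -> float:
    """E[W^k] by explicit multinomial expansion over compositions.

    Exponential-cost reference used to validate the convolution route on
    small problems.
    """
    from itertools import product

    z0 = check_initial_condition(z0, table.m)
    types = np.repeat(np.arange(table.m), z0)
    N = len(types)
    total = 0.0
    for alloc in product(range(k + 1), repeat=N):
        if sum(alloc) != k:
            continue
        coeff = float(np.exp(gammaln(k + 1) - sum(gammaln(a + 1) for a in alloc)))
        term = coeff
        for t, a_n in zip(types, alloc):
            term *= table.xi[t, a_n]
        total += term
    return total


def conditional_moments(w_moments: np.ndarray, q_star: float) -> np.ndarray:
    """Moments of W* = W | W > 0: E[W*^k] = E[W^k] / (1 - q*) for k >= 1."""
    if not 0 <= q_star < 1:
        raise ValueError("q_star must lie in [0, 1)")
    out = np.asarray(w_moments, dtype=float).copy()
    out[1:] = out[1:] / (1.0 - q_star)
    return out
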