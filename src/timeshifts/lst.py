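"""Laplace-Stieltjes transforms of the martingale limit W.

The LST phi_i(theta) = E[exp(-theta W_i)] is evaluated anywhere in the
complex plane in two stages:

1. Inside the disc |theta| <= L(n, eps) a degree-n Taylor expansion in the
   moments is used; Lagrange's remainder bounds its absolute error by
   |theta|^(n+1) E[W_i^(n+1)] / (n+1)! so the radius

       L(n, eps) = ((n+1)! eps / gamma)^(1/(n+1)),
       gamma = max_i E[W_i^(n+1)],

   guarantees error <= eps for every type simultaneously.

2. Outside the disc, the functional equation
   phi(theta) = f~(phi(theta e^(-lam h))) of the h-step embedded process is
   applied kappa = ceil(log(|theta| / L) / (lam h)) times, shrinking the
   argument into the disc.  The embedded progeny generating function
   f~(s) = F(s, h) solves the Kolmogorov backward system

       dF_i/dt = a_i (f_i(F) - F_i),   F(s, 0) = s,

   and kappa applications of F(., h) coincide with one integration of the
   same system over [0, kappa h] (the backward flow is a semigroup), which
   is how the evaluator computes them; `iterate_embedded` performs the
   literal composition.

Discrete-time models use the same scheme with f~ = f, lam = log(rho) and
h = 1 — no ODE solves are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammaln

from .branching import BranchingModel, EigenSystem
from .moments import MomentTable, moment_recursion

_KAPPA_CAP = 10**7


@dataclass
class LSTConfig:
    """Hyper-parameters of the LST evaluation.

    n : Taylor order (number of moments in the expansion).
    h : embedded-process time step.
    eps : target absolute error of the Taylor stage.
    ode_rtol / ode_atol : tolerances of the embedded-pgf integration.
    kappa_margin : extra shrink steps beyond the minimal kappa.  The
        functional-equation bound only requires kappa to be *at least*
        log(|theta|/L)/(lam h); shrinking further multiplies the Taylor
        residual by e^{-(n+1) lam h} per extra step at negligible cost.
        Downstream consumers whose linear functionals of phi carry a large
        weight norm (transform inversion) raise this so that the amplified
        residual stays at the eps level.
    """

    n: int = 30
    h: float = 0.1
    eps: float = 1e-6
    ode_rtol: float = 1e-10
    ode_atol: float = 1e-12
    kappa_margin: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.h <= 0 or self.eps <= 0:
            raise ValueError("need n >= 1, h > 0, eps > 0")
        if self.kappa_margin < 0:
            raise ValueError("kappa_margin must be >= 0")


def error_radius(table: MomentTable, n: int, eps: float) -> float:
    """Radius L(n, eps) of the controlled-error Taylor disc."""
    if table.n_max < n + 1:
        raise ValueError("need moments up to order n + 1")
    gamma = float(np.max(table.xi[:, n + 1]))
    return float(np.exp((gammaln(n + 2) + np.log(eps) - np.log(gamma)) / (n + 1)))


def embedded_pgf(
    model: BranchingModel,
    s: np.ndarray,
    h: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Embedded progeny generating function f~(s) = F(s, h) of a CT-MBP."""
    a = model.lifetime_rates()

    def rhs(t, y):
        return a * (model.pgf_all(y) - y)

    s = np.asarray(s, dtype=complex)
    sol = solve_ivp(rhs, (0.0, h), s, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"embedded pgf integration failed at s = {s}: {sol.message}")
    return sol.y[:, -1]


class LSTEvaluator:
    """Evaluates phi(theta) = (phi_1, ..., phi_m)(theta) for a single model.

    Construction triggers the moment recursion to order n + 1 (the extra
    order feeds the Taylor error bound).
    """

    def __init__(
        self,
        model: BranchingModel,
        eig: EigenSystem | None = None,
        config: LSTConfig | None = None,
        table: MomentTable | None = None,
    ):
        self.model = model
        self.config = config or LSTConfig()
        self.eig = eig or model.eigen()
        n = self.config.n
        if table is None:
            table = moment_recursion(model, self.eig, n + 1)
        if table.n_max < n + 1:
            raise ValueError("moment table too short for the configured Taylor order")
        self.table = table
        self.gamma_bound = float(np.max(table.xi[:, n + 1]))
        self.L = error_radius(table, n, self.config.eps)
        # effective shrink target: margin extra embedded steps inside the disc
        lam_h = self.eig.lam * self.config.h
        self.L_eff = self.L * np.exp(-lam_h * self.config.kappa_margin)
        # Taylor coefficients E[W_i^k]/k!, k = 0..n
        kf = gammaln(np.arange(n + 1) + 1.0)
        self._coeffs = table.xi[:, : n + 1] * np.exp(-kf)[None, :]
        self.n_embedded_applications = 0  # incremented by iterate_embedded only

    # -- Taylor stage -----------------------------------------------------
    def taylor(self, theta) -> np.ndarray:
        """Degree-n Taylor value, shape (..., m); caller keeps |theta| <= L."""
        theta = np.asarray(theta, dtype=complex)
        powers = (-theta[..., None]) ** np.arange(self.config.n + 1)
        return powers @ self._coeffs.T

    def taylor_deriv(self, theta) -> np.ndarray:
        """d/dtheta of the Taylor stage: -sum (-theta)^(k-1) E[W^k]/(k-1)!."""
        theta = np.asarray(theta, dtype=complex)
        ks = np.arange(1, self.config.n + 1)
        powers = (-theta[..., None]) ** (ks - 1)
        return -(powers @ (self._coeffs[:, 1:] * ks).T)

    # -- composition stage ------------------------------------------------
    def kappa(self, theta: complex) -> int:
        """Embedded-pgf applications needed to shrink theta to |.| <= L_eff."""
        r = abs(theta)
        if r <= self.L_eff:
            return 0
        lam_h = self.eig.lam * self.config.h
        k = int(np.ceil(np.log(r / self.L_eff) / lam_h))
        if k > _KAPPA_CAP:
            raise OverflowError(f"kappa = {k} embedded steps required for |theta| = {r:g}")
        return max(k, 0)

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=complex)
        if theta.ndim == 0:
            return self.eval_many(theta[None])[0]
        return self.eval_many(theta)

    def eval_many(self, thetas: np.ndarray, deriv: bool = False):
        """phi at an array of complex points, shape (len(thetas), m).

        Points outside the Taylor disc are propagated jointly: each theta_j
        needs an integration over total time kappa_j * h, which is rescaled
        to unit time (dy/dsigma = T_j * rhs) so one batched adaptive solve
        covers all of them.  With deriv=True the variational system rides
        along and the pair (phi, dphi/dtheta) is returned — the exact
        counterpart of differentiating the inversion formula.
        """
        thetas = np.asarray(thetas, dtype=complex).ravel()
        if self.model.discrete:
            if deriv:
                raise NotImplementedError("derivatives for DT models are not needed")
            return np.array([self._eval_discrete(t) for t in thetas])
        out = np.empty((thetas.size, self.model.m), dtype=complex)
        dout = np.empty_like(out) if deriv else None
        kappas = np.array([self.kappa(t) for t in thetas])
        inside = kappas == 0
        if np.any(inside):
            out[inside] = self.taylor(thetas[inside])
            if deriv:
                dout[inside] = self.taylor_deriv(thetas[inside])
        if np.any(~inside):
            idx = np.flatnonzero(~inside)
            lam, h = self.eig.lam, self.config.h
            T = kappas[idx] * h
            theta_small = thetas[idx] * np.exp(-lam * T)
            y0 = self.taylor(theta_small)  # (B, m)
            if not deriv:
                out[idx] = self._propagate(y0, T)
            else:
                # chain rule through theta_small = theta e^{-lam T}
                d0 = self.taylor_deriv(theta_small) * np.exp(-lam * T)[:, None]
                phi, dphi = self._propagate(y0, T, d0)
                out[idx] = phi
                dout[idx] = dphi
        return (out, dout) if deriv else out

    def _propagate(self, y0: np.ndarray, T: np.ndarray, d0: np.ndarray | None = None):
        """Flow rows of y0 through the backward system for their own times T_j.

        With d0 given, the linearised (variational) flow is integrated
        alongside: d' = T_j a * (J_f(F) d - d), yielding J_flow . d0.
        """
        a = self.model.lifetime_rates()
        B, m = y0.shape
        Tcol = T[:, None]
        model = self.model

        if d0 is None:

            def rhs(sigma, y):
                F = y.reshape(B, m)
                return (Tcol * (a * (model.pgf_all(F) - F))).ravel()

            state0 = y0.ravel()
        else:

            def rhs(sigma, y):
                F = y[: B * m].reshape(B, m)
                D = y[B * m :].reshape(B, m)
                dF = Tcol * (a * (model.pgf_all(F) - F))
                # J_f(F)_ij = (alpha_ij + sum_{k<=l} beta_ikl (d_jk F_l + d_jl F_k)) / a_i
                JD = (
                    D @ model.alpha.T
                    + np.einsum("ikl,...l,...k->...i", model.beta, F, D)
                    + np.einsum("ikl,...k,...l->...i", model.beta, F, D)
                ) / a
                dD = Tcol * (a * (JD - D))
                return np.concatenate([dF.ravel(), dD.ravel()])

            state0 = np.concatenate([y0.ravel(), d0.ravel()])

        sol = solve_ivp(
            rhs,
            (0.0, 1.0),
            state0,
            method="RK45",
            rtol=self.config.ode_rtol,
            atol=self.config.ode_atol,
        )
        if not sol.success:
            raise RuntimeError(f"LST propagation failed: {sol.message}")
        if d0 is None:
            return sol.y[:, -1].reshape(B, m)
        final = sol.y[:, -1]
        return final[: B * m].reshape(B, m), final[B * m :].reshape(B, m)

    def iterate_embedded(self, s: np.ndarray, kappa: int) -> np.ndarray:
        """Apply the embedded pgf f~ literally kappa times (kappa ODE solves)."""
        y = np.asarray(s, dtype=complex)
        for _ in range(kappa):
            y = embedded_pgf(
                self.model, y, self.config.h, self.config.ode_rtol, self.config.ode_atol
            )
            self.n_embedded_applications += 1
        return y

    def _eval_discrete(self, theta: complex) -> np.ndarray:
        k = self.kappa(theta)
        rho = self.eig.rho
        y = self.taylor(np.asarray(theta * rho ** (-k), dtype=complex))
        for _ in range(k):
            y = self.model.pgf_all(y)
        return y


def lst_for_initial(phis: np.ndarray, z0) -> np.ndarray:
    """LST of W for initial counts z0: phi(theta) = prod_i phi_i(theta)^z0_i."""
    phis = np.asarray(phis)
    z0 = np.asarray(z0)
    if phis.shape[-1] != z0.shape[0]:
        raise ValueError("length mismatch between phis and z0")
    return np.prod(phis ** z0.astype(float), axis=-1)
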