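"""The distribution of W recovered from its LST (probability-estimation route).

W mixes an atom of mass q* at zero (ultimate extinction) with an absolutely
continuous part on w > 0:

    G_W(w) = q*                          at w = 0,
    G_W(w) = L^{-1}{ phi(theta)/theta }  for w > 0,

and W* = W | W > 0 has density g(w) = G_W'(w) / (1 - q*).  Inversion uses
the Abate-Whitt Euler nodes; the density is obtained either by direct
inversion of the continuous part's transform phi(theta) - q*, or by the
analytic w-derivative of the inverted CDF via the exact LST derivative
(both modes exposed).
Sampling is inverse-CDF on a monotone PCHIP interpolant of the conditional
CDF over an adaptive quantile-covering grid.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import inversion
from .branching import BranchingModel, check_initial_condition
from .lst import LSTConfig, LSTEvaluator, lst_for_initial
from .moments import conditional_moments, w_moments_from_initial


class WDistribution:
    """CDF / conditional PDF / sampler of W for a given initial condition.

    Parameters
    ----------
    model, z0 : the branching process and initial counts.
    config : LST hyper-parameters (Taylor order, embedded step, tolerance).
    inversion_order : number of Abate-Whitt Euler terms.
    """

    def __init__(
        self,
        model: BranchingModel,
        z0,
        config: LSTConfig | None = None,
        inversion_order: int = inversion.DEFAULT_ORDER,
    ):
        self.model = model
        self.z0 = check_initial_condition(z0, model.m)
        eig = model.eigen()
        config = config or LSTConfig()
        if config.kappa_margin == 0:
            # push the Taylor residual below eps / ||eta||_1 so that the
            # inversion weights cannot amplify it above the eps target
            eta, _ = inversion.euler_nodes(inversion_order)
            amp = float(np.sum(np.abs(eta)))
            margin = int(np.ceil(np.log(amp) / ((config.n + 1) * eig.lam * config.h)))
            config = replace(config, kappa_margin=max(margin, 0))
        self.evaluator = LSTEvaluator(model, eig=eig, config=config)
        self.eig = self.evaluator.eig
        self.lam = self.eig.lam
        self.mu_w = float(self.z0 @ self.eig.u)
        q = model.extinction_probs()
        self.q = q
        self.q_star = float(np.prod(q**self.z0))
        self.inversion_order = inversion_order
        self._cdf_inverse = None

    # -- transforms -------------------------------------------------------
    def lst(self, theta) -> np.ndarray:
        """phi(theta) = prod_i phi_i(theta)^{z0_i}, vectorised over theta."""
        phis = self.evaluator(np.asarray(theta, dtype=complex))
        return lst_for_initial(phis, self.z0)

    def lst_deriv(self, theta) -> np.ndarray:
        """d/dtheta of the product LST (exact, via the variational flow)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=complex))
        phis, dphis = self.evaluator.eval_many(theta, deriv=True)
        tot = lst_for_initial(phis, self.z0)
        return tot * np.sum(self.z0 * dphis / phis, axis=-1)

    def w_moments(self, k_max: int | None = None) -> np.ndarray:
        return w_moments_from_initial(self.evaluator.table, self.z0, k_max)

    def wstar_moments(self, k_max: int | None = None) -> np.ndarray:
        return conditional_moments(self.w_moments(k_max), self.q_star)

    # -- CDF / PDF --------------------------------------------------------
    def invert_cdf(self, w, clip: bool = True) -> np.ndarray:
        """G_W(w) for w > 0 by numerical inversion of phi(theta)/theta."""
        vals = inversion.invert_cdf_from_lst(self.lst, w, self.inversion_order)
        if clip:
            vals = np.clip(vals, 0.0, 1.0)
        return vals

    def cdf(self, w, clip: bool = True) -> np.ndarray:
        """Full mixture CDF: q* at w = 0, inversion for w > 0."""
        w = np.atleast_1d(np.asarray(w, dtype=float))
        if np.any(w < 0):
            raise ValueError("W is nonnegative")
        out = np.full(w.shape, self.q_star)
        pos = w > 0
        if np.any(pos):
            out[pos] = self.invert_cdf(w[pos], clip=clip)
        return out

    def cdf_wstar(self, w) -> np.ndarray:
        """Conditional CDF of W* = W | W > 0."""
        return np.clip((self.cdf(w) - self.q_star) / (1.0 - self.q_star), 0.0, 1.0)

    def pdf_wstar(self, w, mode: str = "density") -> np.ndarray:
        """Density of W* at w > 0.

        mode="density": invert the transform of the continuous part,
        phi(theta) - q*, directly.  mode="derivative": differentiate the
        CDF inversion formula in w analytically, which needs the exact LST
        derivative phi'(theta) (computed by the variational flow):

            d/dw sum Re[(eta_k/beta_k) phi(beta_k/w)]
              = -(1/w^2) sum Re[eta_k phi'(beta_k/w)].
        """
        w = np.atleast_1d(np.asarray(w, dtype=float))
        if np.any(w <= 0):
            raise ValueError("the conditional density lives on w > 0")
        if mode == "density":
            dens = inversion.invert(
                lambda s: self.lst(s) - self.q_star, w, self.inversion_order
            )
        elif mode == "derivative":
            eta, beta = inversion.euler_nodes(self.inversion_order)
            s = beta[None, :] / w[:, None]
            dvals = self.lst_deriv(s.ravel()).reshape(s.shape)
            dens = -(dvals * eta[None, :]).real.sum(axis=1) / w**2
        else:
            raise ValueError("mode must be 'density' or 'derivative'")
        return np.maximum(dens, 0.0) / (1.0 - self.q_star)

    # -- sampling ---------------------------------------------------------
    def _build_inverse_cdf(self, p_lo: float = 1e-4, p_hi: float = 1.0 - 1e-4):
        """Monotone interpolant of the conditional quantile function."""
        mom = self.wstar_moments(2)
        mean = mom[1]
        sd = float(np.sqrt(max(mom[2] - mean**2, 1e-12)))
        w_hi = mean + 10 * sd
        # extend upper end until the target quantile is covered
        for _ in range(60):
            if self.cdf_wstar(np.array([w_hi]))[0] >= p_hi:
                break
            w_hi *= 1.5
        else:
            raise RuntimeError("could not bracket the upper sampling quantile")
        # log-spaced lower end to resolve densities peaking near zero
        grid = np.unique(
            np.concatenate(
                [
                    np.geomspace(w_hi * 1e-6, w_hi / 10, 40),
                    np.linspace(w_hi / 10, w_hi, 80),
                ]
            )
        )
        cvals = self.cdf_wstar(grid)
        cvals = np.maximum.accumulate(cvals)  # isotonic correction of inversion noise
        keep = np.concatenate(([True], np.diff(cvals) > 1e-12))
        grid, cvals = grid[keep], cvals[keep]
        if cvals[0] > p_lo or cvals[-1] < p_hi:
            if cvals[0] > p_lo:
                # push the grid further toward zero
                extra = np.geomspace(grid[0] * 1e-4, grid[0], 20)[:-1]
                ev = np.maximum.accumulate(self.cdf_wstar(extra))
                grid = np.concatenate([extra, grid])
                cvals = np.concatenate([ev, cvals])
                keep = np.concatenate(([True], np.diff(cvals) > 1e-12))
                grid, cvals = grid[keep], cvals[keep]
        self._cdf_inverse = PchipInterpolator(cvals, grid, extrapolate=False)
        self._cdf_range = (float(cvals[0]), float(cvals[-1]))

    def sample_wstar(self, n: int, rng=None) -> np.ndarray:
        """Inverse-CDF samples of W*; reproducible given a seeded Generator."""
        if n < 1:
            raise ValueError("n >= 1 required")
        rng = np.random.default_rng(rng)
        if self._cdf_inverse is None:
            self._build_inverse_cdf()
        lo, hi = self._cdf_range
        u = rng.uniform(lo, hi, size=n)  # body of the distribution; tails clipped
        return np.asarray(self._cdf_inverse(u))

    def export_table(self, path, w_grid) -> None:
        """Delimited text with columns w, cdf, pdf_wstar."""
        w_grid = np.asarray(w_grid, dtype=float)
        pos = w_grid > 0
        pdf = np.zeros_like(w_grid)
        pdf[pos] = self.pdf_wstar(w_grid[pos])
        np.savetxt(
            path,
            np.column_stack([w_grid, self.cdf(w_grid), pdf]),
            delimiter="\t",
            header="w\tcdf\tpdf_wstar",
            comments="",
        )


# -- SIR analytic reference ------------------------------------------------

def sir_analytic_lst(beta: float, gamma: float, theta) -> np.ndarray:
    """Closed-form LST of W for the linear birth-death (SIR) approximation."""
    if beta <= gamma:
        raise ValueError("supercritical SIR requires beta > gamma")
    theta = np.asarray(theta, dtype=complex)
    lam = beta - gamma
    return gamma / beta + (lam / beta) / (1.0 + beta * theta / lam)


def sir_analytic_cdf(beta: float, gamma: float, w) -> np.ndarray:
    """Closed-form CDF of W: atom q = gamma/beta plus Exp(1 - q) tail."""
    if beta <= gamma:
        raise ValueError("supercritical SIR requires beta > gamma")
    w = np.asarray(w, dtype=float)
    q = gamma / beta
    return np.where(w < 0, 0.0, q + (1 - q) * (1 - np.exp(-(1 - q) * np.maximum(w, 0))))


def sir_analytic_pdf_wstar(beta: float, gamma: float, w) -> np.ndarray:
    """Conditional density of W*: Exp(1 - q)."""
    q = gamma / beta
    w = np.asarray(w, dtype=float)
    return (1 - q) * np.exp(-(1 - q) * w)


def cdf_error_metrics(method_vals, exact_vals) -> dict:
    """Grid error summaries between two CDF vectors.

    Returns the summed absolute error (`l1_sum`), its grid average
    (`l1_mean`) and the maximal absolute error (`max`); the two L1
    conventions are both reported since "L1-norm over a grid" is used in
    the literature for either.
    """
    a = np.asarray(method_vals, dtype=float)
    b = np.asarray(exact_vals, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    d = np.abs(a - b)
    return {"l1_sum": float(d.sum()), "l1_mean": float(d.mean()), "max": float(d.max())}
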