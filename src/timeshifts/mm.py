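"""Moment-matching route: a generalised gamma surrogate for W*.

The conditional limit W* is nonnegative, absolutely continuous, unimodal
and possibly heavy-tailed, which the three-parameter generalised gamma
family GG(scale, a1, a2) covers (gamma: a2 = 1; Weibull: a1 = a2;
exponential: a1 = a2 = 1):

    g(w) = a2 / (scale^a1 Gamma(a1/a2)) * w^(a1-1) * exp(-(w/scale)^a2),
    M_k  = scale^k * Gamma((a1 + k)/a2) / Gamma(a1/a2).

Fitting minimises the sum of squared differences between the first five
mantissa-standardised moments (m_k = c_k * 10^eta_k with c_k in [1, 10))
of W* and of the surrogate, so that all orders carry comparable weight.
The induced time-shift tau = log(W*/mu_W)/lam then has the closed-form
density `timeshift_pdf_mm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln


@dataclass
class GGParams:
    """Generalised gamma parameters (scale, shape1 a1, shape2 a2)."""

    gg_scale: float
    gg_shape1: float
    gg_shape2: float
    fit_loss: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.gg_scale, self.gg_shape1, self.gg_shape2) <= 0:
            raise ValueError("generalised gamma parameters must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.gg_scale, self.gg_shape1, self.gg_shape2)


def gg_pdf(p: GGParams, w) -> np.ndarray:
    """Density of GG(scale, a1, a2) at w > 0 (log-gamma stabilised)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("generalised gamma density lives on w > 0")
    b, a1, a2 = p.as_tuple()
    logpdf = (
        np.log(a2)
        - a1 * np.log(b)
        - gammaln(a1 / a2)
        + (a1 - 1) * np.log(w)
        - (w / b) ** a2
    )
    return np.exp(logpdf)


def gg_cdf(p: GGParams, w) -> np.ndarray:
    """CDF via the regularised lower incomplete gamma function."""
    w = np.asarray(w, dtype=float)
    b, a1, a2 = p.as_tuple()
    return gammainc(a1 / a2, np.maximum(w, 0) ** a2 / b**a2)


def gg_moment(p: GGParams, k) -> np.ndarray:
    """k-th raw moment, k >= 1."""
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("moment order must be positive")
    b, a1, a2 = p.as_tuple()
    return np.exp(k * np.log(b) + gammaln((a1 + k) / a2) - gammaln(a1 / a2))


def sample_gg(p: GGParams, n: int, rng=None) -> np.ndarray:
    """Exact sampling: if X ~ Gamma(a1/a2, 1) then scale * X^(1/a2) ~ GG."""
    rng = np.random.default_rng(rng)
    b, a1, a2 = p.as_tuple()
    return b * rng.gamma(a1 / a2, 1.0, size=n) ** (1.0 / a2)


def standardize_moments(moments) -> tuple[np.ndarray, np.ndarray]:
    """Mantissa/exponent split m_k = c_k * 10^eta_k, c_k in [1, 10)."""
    m = np.asarray(moments, dtype=float)
    if np.any(m <= 0):
        raise ValueError("moments must be positive")
    eta = np.floor(np.log10(m)).astype(int)
    c = m / 10.0**eta
    # guard against log10 rounding at decade boundaries
    low = c < 1.0
    eta[low] -= 1
    c[low] *= 10.0
    high = c >= 10.0
    eta[high] += 1
    c[high] /= 10.0
    return c, eta


def fit_gg(moments_wstar) -> GGParams:
    """Fit GG to the first five moments of W* by standardised least squares.

    Multi-start bounded quasi-Newton on log-parameters: one start at the
    exponential point (1, 1, mean), one at the gamma method-of-moments
    point, plus a stretched-tail start; the best result is polished with
    Nelder-Mead when needed.
    """
    m = np.asarray(moments_wstar, dtype=float)
    if m.shape[0] != 5:
        raise ValueError("exactly the first five moments are matched")
    c, eta = standardize_moments(m)
    scale10 = 10.0**eta
    ks = np.arange(1.0, 6.0)

    def loss(logp):
        b, a1, a2 = np.exp(logp)
        mk = np.exp(ks * np.log(b) + gammaln((a1 + ks) / a2) - gammaln(a1 / a2))
        return float(np.sum((c - mk / scale10) ** 2))

    mean = m[0]
    var = max(m[1] - mean**2, 1e-12 * mean**2)
    starts = [
        np.log([mean, 1.0, 1.0]),  # exponential special case
        np.log([var / mean, mean**2 / var, 1.0]),  # gamma method of moments
        np.log([mean, 2.0, 0.7]),  # heavier tail
    ]
    best = None
    for x0 in starts:
        res = minimize(loss, x0, method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    if best.fun > 1e-12:
        res = minimize(loss, best.x, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 4000})
        if res.fun < best.fun:
            best = res
    b, a1, a2 = np.exp(best.x)
    return GGParams(b, a1, a2, fit_loss=float(best.fun), converged=best.fun < 1e-10)


def timeshift_pdf_mm(p: GGParams, lam: float, mu_w: float, tau) -> np.ndarray:
    """Density of tau* = log(W*/mu_W)/lam under the fitted GG surrogate.

    g(tau) = a2 lam mu^a1 / (b^a1 Gamma(a1/a2))
             * exp(-(mu e^{lam tau} / b)^a2 + a1 lam tau).
    """
    if lam <= 0 or mu_w <= 0:
        raise ValueError("lam and mu_w must be positive")
    tau = np.asarray(tau, dtype=float)
    b, a1, a2 = p.as_tuple()
    lognorm = np.log(a2) + np.log(lam) + a1 * (np.log(mu_w) - np.log(b)) - gammaln(a1 / a2)
    return np.exp(lognorm - (mu_w * np.exp(lam * tau) / b) ** a2 + a1 * lam * tau)
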