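"""Random time-shifts and hybrid macroscopic trajectories.

The persistent effect of early-time stochasticity on a macroscopic
trajectory is a translation of the time axis: with growth rate lam and
mu_W = E[W] = z0 . u,

    tau = log(W / mu_W) / lam,

so a stochastic path with W above its mean runs ahead of the deterministic
curve (tau > 0) and the deterministic solution zeta evaluated at t + tau
approximates the path.  Generating a hybrid ensemble therefore needs one
ODE solve and n draws of the scalar tau.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .ctmc import CTMCModel
from .mm import GGParams, gg_cdf, sample_gg, timeshift_pdf_mm
from .wdist import WDistribution

# module-level ODE solve counter: lets callers assert that replicating a
# hybrid ensemble costs a single deterministic solve
N_ODE_SOLVES = 0


def w_to_tau(w, lam: float, mu_w: float) -> np.ndarray:
    """tau = (log w - log mu_W) / lam; defined for surviving paths (w > 0)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("extinct paths (w <= 0) carry no time-shift")
    if lam <= 0 or mu_w <= 0:
        raise ValueError("lam and mu_w must be positive")
    return (np.log(w) - np.log(mu_w)) / lam


def tau_to_w(tau, lam: float, mu_w: float) -> np.ndarray:
    return mu_w * np.exp(lam * np.asarray(tau, dtype=float))


class TimeShiftDistribution:
    """Law of tau* (conditioned on non-extinction) under the PE or MM backend.

    backend : WDistribution (probability-estimation route) or GGParams
        (fitted generalised gamma surrogate).
    """

    def __init__(self, backend, lam: float | None = None, mu_w: float | None = None):
        self.backend = backend
        if isinstance(backend, WDistribution):
            self.kind = "pe"
            self.lam = backend.lam if lam is None else lam
            self.mu_w = backend.mu_w if mu_w is None else mu_w
        elif isinstance(backend, GGParams):
            self.kind = "mm"
            if lam is None or mu_w is None:
                raise ValueError("the MM backend needs explicit lam and mu_w")
            self.lam, self.mu_w = lam, mu_w
        else:
            raise TypeError("backend must be a WDistribution or GGParams")

    def pdf(self, tau) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        w = tau_to_w(tau, self.lam, self.mu_w)
        jac = self.mu_w * self.lam * np.exp(self.lam * tau)
        if self.kind == "pe":
            return self.backend.pdf_wstar(w) * jac
        return timeshift_pdf_mm(self.backend, self.lam, self.mu_w, tau)

    def cdf(self, tau) -> np.ndarray:
        w = tau_to_w(tau, self.lam, self.mu_w)
        if self.kind == "pe":
            return self.backend.cdf_wstar(w)
        return gg_cdf(self.backend, w)

    def sample(self, n: int, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng)
        if self.kind == "pe":
            w = self.backend.sample_wstar(n, rng)
        else:
            w = sample_gg(self.backend, n, rng)
        return w_to_tau(w, self.lam, self.mu_w)


class Trajectory:
    """Dense deterministic solution with exact-at-nodes interpolation.

    Stores the forward (and optional backward) `solve_ivp` dense outputs of
    the fluid-limit ODE; call it at arbitrary times within the integrated
    window.  States are densities; multiply by `scale` for counts.
    """

    def __init__(self, fwd_sol, back_sol=None, scale: float = 1.0, offset: float = 0.0):
        self._fwd = fwd_sol
        self._back = back_sol
        self.scale = scale
        self.offset = offset  # evaluation shift: self(t) = base(t + offset)
        self.t_min = (-back_sol.t[-1] if back_sol is not None else fwd_sol.t[0]) - offset
        self.t_max = fwd_sol.t[-1] - offset
        self.t_fwd_start = fwd_sol.t[0] - offset  # where the forward solve begins
        self.t_grid = fwd_sol.t - offset

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float) + self.offset
        if np.any(t < self.t_min + self.offset - 1e-9) or np.any(
            t > self.t_max + self.offset + 1e-9
        ):
            raise ValueError(
                f"evaluation outside the integrated window "
                f"[{self.t_min:g}, {self.t_max:g}] (after shifting); extend t_back/t_span"
            )
        t = np.atleast_1d(t)
        out = np.empty((t.size, self._fwd.y.shape[0]))
        neg = t < 0
        if np.any(neg):
            out[neg] = self._back.sol(-t[neg]).T
        if np.any(~neg):
            out[~neg] = self._fwd.sol(t[~neg]).T
        return out.squeeze()

    def shifted(self, tau: float) -> "Trajectory":
        """The trajectory t -> self(t + tau); no re-integration."""
        return Trajectory(self._fwd, self._back, self.scale, self.offset + tau)

    def first_crossing(self, coord: int, level: float) -> float:
        """First time the count of `coord` reaches `level` (counts, not density).

        Only the forward trajectory is scanned: the backward extension
        exists for evaluating shifted replicates, not for thresholds (the
        backward flow of an off-manifold initial condition is not a
        population trajectory).
        """
        target = level / self.scale
        tg = np.linspace(self.t_fwd_start, self.t_max, 2001)
        vals = np.atleast_2d(self(tg))[:, coord]
        above = np.flatnonzero(vals >= target)
        if above.size == 0:
            raise ValueError("deterministic trajectory never reaches the requested level")
        i = above[0]
        if i == 0:
            return float(tg[0])
        f = lambda t: float(np.atleast_1d(self(t))[coord] - target)
        return float(brentq(f, tg[i - 1], tg[i], xtol=1e-10))

    def peak_time(self, coord: int) -> float:
        """Golden-section refinement of the interpolant's maximum for one state."""
        tg = np.linspace(self.t_min, self.t_max, 2001)
        vals = np.atleast_2d(self(tg))[:, coord]
        i = int(np.argmax(vals))
        lo = tg[max(i - 1, 0)]
        hi = tg[min(i + 1, len(tg) - 1)]
        if lo == hi:
            return float(tg[i])
        res = minimize_scalar(
            lambda t: -float(np.atleast_1d(self(t))[coord]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    def export(self, path, times=None) -> None:
        times = self.t_grid if times is None else np.asarray(times, dtype=float)
        states = np.atleast_2d(self(times))
        np.savetxt(
            path,
            np.column_stack([times, states]),
            delimiter="\t",
            header="t\t" + "\t".join(f"x{i}" for i in range(states.shape[1])),
            comments="",
        )


def deterministic_solution(
    ctmc: CTMCModel,
    t_span: tuple[float, float],
    t_back: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the fluid-limit density ODE from x0/scale.

    `t_back` > 0 additionally integrates backwards from the initial
    condition so that shifted trajectories can be evaluated at t + tau < 0
    (the flow near the unstable equilibrium is well defined backwards).
    """
    global N_ODE_SOLVES
    x0 = ctmc.x0 / ctmc.scale

    def rhs(t, x):
        return ctmc.density_drift(x)

    fwd = solve_ivp(rhs, t_span, x0, dense_output=True, rtol=rtol, atol=atol, method="LSODA")
    if not fwd.success:
        raise RuntimeError(f"deterministic solve failed: {fwd.message}")
    N_ODE_SOLVES += 1
    back = None
    if t_back > 0:
        back = solve_ivp(
            lambda t, x: -ctmc.density_drift(x),
            (0.0, t_back),
            x0,
            dense_output=True,
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        if not back.success:
            raise RuntimeError(f"backward extension failed: {back.message}")
    return Trajectory(fwd, back, scale=ctmc.scale)


def hybrid_ensemble(
    traj: Trajectory, shift_dist: TimeShiftDistribution, n: int, rng=None
) -> tuple[np.ndarray, list[Trajectory]]:
    """n shifted replicates of one deterministic solution.

    Returns the tau draws and the shifted trajectory handles; no further
    ODE solves are performed.
    """
    taus = shift_dist.sample(n, rng)
    return taus, [traj.shifted(float(tau)) for tau in taus]
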