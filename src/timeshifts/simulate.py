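"""Exact stochastic simulation and empirical estimators.

The Gillespie algorithm provides the ground truth against which every
distributional output is validated: extinction fractions against the pgf
fixed point, martingale means, empirical W samples against the inverted
LST, and empirical threshold-crossing time-shifts against the computed
tau* law.  Two implementations are provided: a plain-Python event loop
that records full trajectories (reference, small problems) and a
numba-compiled mass-action kernel used for large ensembles, which only
tracks the quantities the estimators need (final state, threshold-crossing
time, extinction flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .branching import BranchingModel
from .ctmc import CTMCModel
from .fixtures import bp_as_ctmc
from .shift import Trajectory


@dataclass
class SimulationResult:
    times: np.ndarray
    states: np.ndarray  # (n_events + 1, dim)
    extinct: bool
    hit_time: float | None = None


def gillespie(
    ctmc: CTMCModel,
    t_max: float,
    rng=None,
    absorb: np.ndarray | None = None,
    threshold: tuple[int, float] | None = None,
    max_events: int = 10**7,
) -> SimulationResult:
    """Exact jump-chain simulation recording every event (reference path).

    absorb : optional boolean mask; the run stops (extinct) when the masked
        coordinates sum to zero.
    threshold : optional (coord, level); the run stops when that count
        reaches the level, recording the crossing time.
    """
    rng = np.random.default_rng(rng)
    x = ctmc.x0.astype(np.int64).copy()
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    extinct = False
    hit = None
    for _ in range(max_events):
        rates = ctmc.rates(x)
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise RuntimeError(f"invalid rates {rates} at state {x}")
        total = rates.sum()
        if total == 0:
            extinct = absorb is None or x[absorb].sum() == 0
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        e = rng.choice(len(rates), p=rates / total)
        x += ctmc.events[e].delta
        times.append(t)
        states.append(x.copy())
        if threshold is not None and x[threshold[0]] >= threshold[1]:
            hit = t
            break
        if absorb is not None and x[absorb].sum() == 0:
            extinct = True
            break
    else:
        raise RuntimeError("max_events exceeded")
    return SimulationResult(np.array(times), np.array(states), extinct, hit)


@njit(cache=False)
def _ssa_kernel(x0, deltas, coeffs, orders, t_max, thresh_coord, thresh_level, absorb, pop_cap, seed):
    """Mass-action SSA; returns (t, x_final, hit_time, extinct_flag)."""
    np.random.seed(seed)
    dim = x0.shape[0]
    n_ev = coeffs.shape[0]
    x = x0.copy()
    t = 0.0
    hit = -1.0
    extinct = False
    rates = np.empty(n_ev)
    while True:
        total = 0.0
        for e in range(n_ev):
            r = coeffs[e]
            for d in range(dim):
                o = orders[e, d]
                for _ in range(o):
                    r *= x[d]
            rates[e] = r
            total += r
        if total <= 0.0:
            ab = 0
            for d in range(dim):
                if absorb[d]:
                    ab += x[d]
            extinct = ab == 0
            break
        t += -np.log(np.random.random()) / total
        if t > t_max:
            t = t_max
            break
        u = np.random.random() * total
        acc = 0.0
        pick = n_ev - 1
        for e in range(n_ev):
            acc += rates[e]
            if u <= acc:
                pick = e
                break
        for d in range(dim):
            x[d] += deltas[pick, d]
        if thresh_coord >= 0 and x[thresh_coord] >= thresh_level:
            hit = t
            break
        ab = 0
        for d in range(dim):
            if absorb[d]:
                ab += x[d]
        if ab == 0:
            extinct = True
            break
        if pop_cap > 0 and ab >= pop_cap:
            break  # survival is certain for practical purposes
    return t, x, hit, extinct


def run_ssa(
    ctmc: CTMCModel,
    t_max: float,
    seed: int,
    absorb_coords=None,
    threshold: tuple[int, float] | None = None,
    pop_cap: int = 0,
):
    """One fast SSA run; see `_ssa_kernel` for the returned tuple."""
    deltas, coeffs, orders = ctmc.arrays()
    absorb = np.zeros(ctmc.state_dim, dtype=np.bool_)
    if absorb_coords is not None:
        absorb[np.asarray(absorb_coords, dtype=int)] = True
    else:
        absorb[:] = True
    tc, tl = (threshold if threshold is not None else (-1, 0.0))
    return _ssa_kernel(
        ctmc.x0.astype(np.int64),
        deltas,
        coeffs,
        orders,
        float(t_max),
        int(tc),
        float(tl),
        absorb,
        int(pop_cap),
        int(seed),
    )


def empirical_timeshift(
    ctmc: CTMCModel,
    det_traj: Trajectory,
    coord: int,
    reps: int,
    rng=None,
    threshold_frac: float = 0.05,
    threshold_count: float | None = None,
    absorb_coords=None,
    t_max: float = 1e4,
) -> tuple[np.ndarray, int, int]:
    """Threshold-crossing time-shift samples tau_hat = t_det - t_sim.

    For each surviving replicate, t_sim is the first time count `coord`
    reaches the threshold (either `threshold_frac * scale` or an absolute
    `threshold_count`); extinct replicates are discarded and redrawn until
    `reps` survivors are collected.  Returns (tau_samples, n_extinct,
    n_total_runs).
    """
    rng = np.random.default_rng(rng)
    level = threshold_count if threshold_count is not None else threshold_frac * ctmc.scale
    t_det = det_traj.first_crossing(coord, level)
    taus = np.empty(reps)
    got = 0
    n_ext = 0
    n_tot = 0
    max_runs = 1000 + 100 * reps
    while got < reps:
        if n_tot >= max_runs:
            raise RuntimeError("too many extinct replicates; check supercriticality")
        seed = int(rng.integers(0, 2**31 - 1))
        _, _, hit, extinct = run_ssa(
            ctmc, t_max, seed, absorb_coords=absorb_coords, threshold=(coord, level)
        )
        n_tot += 1
        if hit >= 0:
            taus[got] = t_det - hit
            got += 1
        else:
            n_ext += 1
    return taus, n_ext, n_tot


def empirical_w(
    bp: BranchingModel,
    z0,
    t_end: float,
    reps: int,
    rng=None,
) -> np.ndarray:
    """Samples of W from surviving branching-process paths at time t_end.

    Each coordinate of e^{-lam t} Z(t) estimates W v_i, so the coordinates
    are divided by v_i and averaged.
    """
    rng = np.random.default_rng(rng)
    eig = bp.eigen()
    ctmc = bp_as_ctmc(bp, z0)
    out = []
    scale = np.exp(-eig.lam * t_end)
    for _ in range(reps):
        seed = int(rng.integers(0, 2**31 - 1))
        t, x, _, extinct = run_ssa(ctmc, t_end, seed)
        if extinct or x.sum() == 0:
            continue
        out.append(scale * float(np.mean(x / eig.v)))
    return np.array(out)


def extinction_fraction(
    bp: BranchingModel, z0, reps: int, rng=None, t_max: float = 1e4, pop_cap: int = 1000
) -> float:
    """Fraction of branching-process runs that die out.

    Runs whose population reaches `pop_cap` are counted as surviving (for a
    supercritical process the residual extinction probability from a
    population that large is negligible, of order q^pop_cap).
    """
    rng = np.random.default_rng(rng)
    ctmc = bp_as_ctmc(bp, z0)
    n_ext = 0
    for _ in range(reps):
        seed = int(rng.integers(0, 2**31 - 1))
        _, x, _, extinct = run_ssa(ctmc, t_max, seed, pop_cap=pop_cap)
        if extinct:
            n_ext += 1
    return n_ext / reps
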