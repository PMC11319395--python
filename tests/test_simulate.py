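"""Gillespie simulation layer and empirical estimators against exact oracles."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import expon, kstest, ks_2samp

from timeshifts import fixtures
from timeshifts.ctmc import CTMCModel, Event
from timeshifts.simulate import (
    empirical_timeshift,
    empirical_w,
    extinction_fraction,
    gillespie,
    run_ssa,
)
from timeshifts.shift import deterministic_solution

from conftest import SIR_Q


def test_pure_death_mean_extinction_time(rng):
    """Single individual dying at rate r: extinction time ~ Exp(r)."""
    r = 2.0
    ctmc = CTMCModel([Event([-1], r, [1], "death")], scale=1.0, x0=[1])
    times = np.array(
        [run_ssa(ctmc, 1e3, int(rng.integers(2**31)))[0] for _ in range(4000)]
    )
    se = times.std() / np.sqrt(len(times))
    assert abs(times.mean() - 1 / r) < 3 * se


def sir_final_size_pmf(N, I0, beta, gamma):
    """Exact final-size distribution by forward propagation of the jump chain.

    From state (s, i) the next event is an infection with probability
    (beta s / (N-1)) / (beta s / (N-1) + gamma), independent of i > 0.
    """
    mass = {(N - I0, I0): 1.0}
    final = {}
    # topological order: infections lower s, recoveries lower i at fixed s
    for s in range(N - I0, -1, -1):
        for i in range(N, 0, -1):
            p = mass.pop((s, i), 0.0)
            if p == 0.0:
                continue
            lam_inf = beta * s / (N - 1)
            p_inf = lam_inf / (lam_inf + gamma) if s > 0 else 0.0
            if s > 0:
                mass[(s - 1, i + 1)] = mass.get((s - 1, i + 1), 0.0) + p * p_inf
            mass[(s, i - 1)] = mass.get((s, i - 1), 0.0) + p * (1 - p_inf)
        p_done = mass.pop((s, 0), 0.0)
        if p_done:
            final[N - I0 - s] = final.get(N - I0 - s, 0.0) + p_done
    sizes = np.array(sorted(final))
    return sizes, np.array([final[s] for s in sizes])


def test_sir_small_population_final_size(rng):
    N, I0, beta, gamma = 30, 1, 0.95, 0.5
    sizes, pmf = sir_final_size_pmf(N, I0, beta, gamma)
    exact_mean = float(sizes @ pmf)
    _, ctmc = fixtures.sir(beta, gamma, N=N, I0=I0)
    finals = []
    for _ in range(4000):
        _, x, _, _ = run_ssa(ctmc, 1e4, int(rng.integers(2**31)), absorb_coords=[1])
        finals.append((N - I0) - x[0])
    finals = np.array(finals)
    se = finals.std() / np.sqrt(len(finals))
    assert abs(finals.mean() - exact_mean) < 3 * se


def test_seeded_reproducibility(seir_pair):
    _, ctmc = seir_pair
    a = run_ssa(ctmc, 5.0, 123, absorb_coords=[1, 2])
    b = run_ssa(ctmc, 5.0, 123, absorb_coords=[1, 2])
    assert a[0] == b[0] and np.array_equal(a[1], b[1])
    r1 = gillespie(fixtures.sir(N=200, I0=2)[1], 3.0, np.random.default_rng(9))
    r2 = gillespie(fixtures.sir(N=200, I0=2)[1], 3.0, np.random.default_rng(9))
    assert np.array_equal(r1.states, r2.states)


def test_ssa_mean_matches_matrix_exponential(sir_pair, rng):
    """Short-horizon BP mean: E[Z(t)] = z0 expm(Omega t), within 3 SE."""
    bp, _ = sir_pair
    t = 2.0
    expected = float((np.array([1.0]) @ expm(bp.growth_matrix() * t))[0])
    ctmc = fixtures.bp_as_ctmc(bp, [1])
    finals = np.array(
        [run_ssa(ctmc, t, int(rng.integers(2**31)))[1][0] for _ in range(4000)]
    )
    se = finals.std() / np.sqrt(len(finals))
    assert abs(finals.mean() - expected) < 3 * se


def test_martingale_mean_is_flat(sir_pair, rng):
    """e^{-lam t} E[Z(t)] stays at z0 . u across horizons."""
    bp, _ = sir_pair
    lam = bp.eigen().lam
    ctmc = fixtures.bp_as_ctmc(bp, [1])
    for t in (5.0, 10.0):
        vals = np.array(
            [run_ssa(ctmc, t, int(rng.integers(2**31)))[1][0] for _ in range(3000)]
        ) * np.exp(-lam * t)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * se


def test_extinction_fraction_matches_q(sir_pair, seir_pair, innate_pair, rng):
    from scipy.stats import binom

    for (bp, _), z0, reps in (
        (sir_pair, [1], 3000),
        (seir_pair, [1, 0], 3000),
        (innate_pair, [1, 0, 0], 1500),
    ):
        q_star = bp.extinction_prob_initial(z0)
        frac = extinction_fraction(bp, z0, reps, rng)
        lo, hi = binom.ppf([0.005, 0.995], reps, q_star) / reps
        assert lo <= frac <= hi


def test_empirical_w_matches_exponential_limit(sir_pair, rng):
    bp, _ = sir_pair
    w = empirical_w(bp, [1], t_end=20.0, reps=3 * 10**4, rng=rng)
    mean = 1 / (1 - SIR_Q)
    se = w.std() / np.sqrt(len(w))
    assert abs(w.mean() - mean) < 3 * se
    assert kstest(w, expon(scale=mean).cdf).statistic < 0.02


def test_empirical_w_projections_agree_across_types(seir_pair, rng):
    """Both rescaled coordinates estimate the same scalar W (W v structure)."""
    bp, _ = seir_pair
    eig = bp.eigen()
    ctmc = fixtures.bp_as_ctmc(bp, [1, 0])
    t_end = 40.0
    w_by_coord = ([], [])
    for _ in range(4000):
        _, x, _, extinct = run_ssa(ctmc, t_end, int(rng.integers(2**31)))
        if x.sum() == 0:
            continue
        for i in (0, 1):
            w_by_coord[i].append(np.exp(-eig.lam * t_end) * x[i] / eig.v[i])
    assert ks_2samp(w_by_coord[0], w_by_coord[1]).pvalue > 0.05


def test_timeshift_translation_invariance(seir_pair, rng):
    """Moving the deterministic clock by c moves every tau-hat by exactly c."""
    _, ctmc = fixtures.seir(N=10**4)
    traj = deterministic_solution(ctmc, (0.0, 400.0), t_back=20.0)
    seed = int(rng.integers(2**31))
    t1, _, _ = empirical_timeshift(
        ctmc, traj, 2, 60, np.random.default_rng(seed), absorb_coords=[1, 2]
    )
    c = 3.25
    t2, _, _ = empirical_timeshift(
        ctmc, traj.shifted(-c), 2, 60, np.random.default_rng(seed), absorb_coords=[1, 2]
    )
    assert np.allclose(t2 - t1, c, atol=1e-8)


def test_conditioning_by_resampling_equals_post_hoc_filtering(sir_pair, rng):
    """Discard-and-redraw vs filter-afterwards give the same tau-hat law."""
    _, ctmc = fixtures.sir(N=2000, I0=1)
    traj = deterministic_solution(ctmc, (0.0, 100.0), t_back=20.0)
    level = 0.05 * ctmc.scale
    t_det = traj.first_crossing(1, level)
    resampled, _, _ = empirical_timeshift(
        ctmc, traj, 1, 400, np.random.default_rng(11), absorb_coords=[1]
    )
    post_hoc = []
    rng2 = np.random.default_rng(12)
    while len(post_hoc) < 400:
        _, _, hit, _ = run_ssa(
            ctmc, 1e4, int(rng2.integers(2**31)), absorb_coords=[1], threshold=(1, level)
        )
        if hit >= 0:
            post_hoc.append(t_det - hit)
    assert ks_2samp(resampled, np.array(post_hoc)).pvalue > 0.01


def test_event_cap_guard():
    runaway = CTMCModel([Event([1], 1.0, [0], "birth")], scale=1.0, x0=[1])
    with pytest.raises(RuntimeError):
        gillespie(runaway, 1e6, np.random.default_rng(0), max_events=100)
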