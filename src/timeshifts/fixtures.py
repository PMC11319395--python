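"""The three study models: SIR, SEIR, and a within-host innate-response model.

Each fixture returns the pair (BranchingModel, CTMCModel): the full
density-dependent CTMC and its branching-process linearisation about the
disease-free (respectively infection-free) state.  The linearisation freezes
the susceptible pool at its initial size, making every rate linear in the
branching types, exactly as one does by hand when reading rates off the
model table.
"""

from __future__ import annotations

import numpy as np

from .branching import BranchingModel
from .ctmc import CTMCModel, Event


def sir(beta: float = 0.95, gamma: float = 0.5, N: float = 1e6, I0: int = 1):
    """SIR epidemic.  BP approximation: one type (infectious), a linear
    birth-death process with birth rate beta and death rate gamma.

    CTMC state (S, I); infection rate beta*S*I/(N-1), recovery rate gamma*I.
    """
    if beta <= 0 or gamma <= 0:
        raise ValueError("rates must be positive")
    m = 1
    nu = np.array([gamma])
    alpha = np.zeros((m, m))
    bq = np.zeros((m, m, m))
    bq[0, 0, 0] = beta  # I -> I + I at rate beta (split into two type-1)
    bp = BranchingModel(nu, alpha, bq)
    ctmc = CTMCModel(
        events=[
            Event([-1, 1], beta / (N - 1), [1, 1], "infection"),
            Event([0, -1], gamma, [0, 1], "recovery"),
        ],
        scale=N,
        x0=[int(N) - I0, I0],
        species=["S", "I"],
    )
    return bp, ctmc


def seir(
    beta: float = 0.56,
    sigma: float = 0.5,
    gamma: float = 0.33,
    N: float = 1e6,
    E0: int = 1,
    I0: int = 0,
):
    """SEIR epidemic.  BP types (E, I) = (1, 2):

    f1(s) = s2  (an exposed individual becomes infectious, a1 = sigma),
    f2(s) = (gamma + beta*s1*s2) / (beta + gamma).
    """
    if min(beta, sigma, gamma) <= 0:
        raise ValueError("rates must be positive")
    m = 2
    nu = np.array([0.0, gamma])
    alpha = np.zeros((m, m))
    alpha[0, 1] = sigma
    bq = np.zeros((m, m, m))
    bq[1, 0, 1] = beta  # I -> E + I (new exposure) at rate beta
    bp = BranchingModel(nu, alpha, bq)
    ctmc = CTMCModel(
        events=[
            Event([-1, 1, 0], beta / (N - 1), [1, 0, 1], "exposure"),
            Event([0, -1, 1], sigma, [0, 1, 0], "progression"),
            Event([0, 0, -1], gamma, [0, 0, 1], "recovery"),
        ],
        scale=N,
        x0=[int(N) - E0 - I0, E0, I0],
        species=["S", "E", "I"],
    )
    return bp, ctmc


INNATE_DEFAULTS = dict(
    beta1=2.0,  # infection of target cells by virions
    beta2=1.6,  # cell-to-cell infection
    sigma=4.0,  # eclipse-phase progression
    eta=1.0,  # death of eclipse-phase cells
    gamma=1.7,  # removal of infectious cells
    p_V=45.3,  # virion production
    c_V=10.0,  # virion clearance
    p_A=6.0,  # interferon production
    c_A=3.0,  # interferon clearance
    rho_R=104.0,  # target cells becoming refractory (per interferon)
    delta_R=4.4e-3,  # refractory cells reverting to target
)


def innate(U0: float = 8e7, K: float | None = None, E0: int = 1, **params):
    """Within-host viral dynamics with an innate (interferon) response.

    CTMC state (U, R, E, I, V, A): target cells, refractory cells,
    eclipse-phase cells, infectious cells, virions, interferons.  The BP
    approximation near (U0, 0, ..., 0) keeps only (E, I, V) = types (1,2,3)
    with, writing bbar_i = beta_i * U0 / K,

        f1 = (eta + sigma*s2) / (sigma + eta)
        f2 = (gamma + p_V*s2*s3 + bbar2*s1*s2) / (gamma + p_V + bbar2)
        f3 = (c_V + bbar1*s1) / (bbar1 + c_V)

    The refractory/interferon loop does not enter the linearisation: with a
    full target-cell pool the immune response is not yet active.
    """
    p = dict(INNATE_DEFAULTS)
    unknown = set(params) - set(p)
    if unknown:
        raise ValueError(f"unknown innate parameters: {sorted(unknown)}")
    p.update(params)
    if K is None:
        K = U0
    bbar1 = p["beta1"] * U0 / K
    bbar2 = p["beta2"] * U0 / K

    m = 3
    nu = np.array([p["eta"], p["gamma"], p["c_V"]])
    alpha = np.zeros((m, m))
    alpha[0, 1] = p["sigma"]  # E -> I
    alpha[2, 0] = bbar1  # V infects a cell: V -> E (virion consumed)
    bq = np.zeros((m, m, m))
    bq[1, 1, 2] = p["p_V"]  # I -> I + V
    bq[1, 0, 1] = bbar2  # I -> E + I (cell-to-cell infection)
    bp = BranchingModel(nu, alpha, bq)

    U, R, E, I, V, A = range(6)

    def ev(delta, coeff, orders, name):
        d = np.zeros(6, dtype=int)
        o = np.zeros(6, dtype=int)
        for idx, val in delta:
            d[idx] = val
        for idx, val in orders:
            o[idx] = val
        return Event(d, coeff, o, name)

    ctmc = CTMCModel(
        events=[
            ev([(U, -1), (E, 1), (V, -1)], p["beta1"] / K, [(U, 1), (V, 1)], "virion infection"),
            ev([(U, -1), (E, 1)], p["beta2"] / K, [(U, 1), (I, 1)], "cell-to-cell infection"),
            ev([(U, -1), (R, 1)], p["rho_R"] / K, [(U, 1), (A, 1)], "refractory"),
            ev([(U, 1), (R, -1)], p["delta_R"], [(R, 1)], "revert"),
            ev([(E, -1), (I, 1)], p["sigma"], [(E, 1)], "progression"),
            ev([(E, -1)], p["eta"], [(E, 1)], "eclipse death"),
            ev([(I, -1)], p["gamma"], [(I, 1)], "removal"),
            ev([(V, 1)], p["p_V"], [(I, 1)], "virion production"),
            ev([(V, -1)], p["c_V"], [(V, 1)], "virion clearance"),
            ev([(A, 1)], p["p_A"], [(I, 1)], "interferon production"),
            ev([(A, -1)], p["c_A"], [(A, 1)], "interferon clearance"),
        ],
        scale=K,
        x0=[int(U0) - E0, 0, E0, 0, 0, 0],
        species=["U", "R", "E", "I", "V", "A"],
    )
    return bp, ctmc


def bp_as_ctmc(model: BranchingModel, z0) -> CTMCModel:
    """Represent a CT-MBP as a (linear) mass-action CTMC for exact simulation.

    Each branching rule becomes one reaction channel with rate proportional
    to the count of the parent type.
    """
    if model.discrete:
        raise ValueError("only continuous-time models can be simulated as CTMCs")
    m = model.m
    events = []
    eye = np.eye(m, dtype=int)
    for i in range(m):
        if model.nu[i] > 0:
            events.append(Event(-eye[i], model.nu[i], eye[i], f"death {i}"))
        for j in range(m):
            if model.alpha[i, j] > 0:
                events.append(Event(eye[j] - eye[i], model.alpha[i, j], eye[i], f"{i}->{j}"))
        for k in range(m):
            for l in range(k, m):
                if model.beta[i, k, l] > 0:
                    events.append(
                        Event(
                            eye[k] + eye[l] - eye[i],
                            model.beta[i, k, l],
                            eye[i],
                            f"{i}->{k}+{l}",
                        )
                    )
    z0 = np.asarray(z0, dtype=int)
    return CTMCModel(events=events, scale=1.0, x0=z0, species=[f"Z{i}" for i in range(m)])
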