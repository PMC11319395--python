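"""Density-dependent continuous-time Markov chains in mass-action form.

Every fixture in this package is a population CTMC whose event rates are
mass-action monomials, ``rate_e(X) = c_e * prod_i X_i^{o_ei}``.  Storing the
coefficient and the vector of reactant orders (instead of opaque rate
callables) lets the same structure drive the exact Gillespie kernel, the
branching-process linearisation checks, and the fluid-limit ODE: with system
size K and density x = X / K, the drift is

    dx/dt = sum_e delta_e * c_e * K^(|o_e| - 1) * prod_i x_i^{o_ei},

which is finite and K-free exactly when the rates are density dependent
(c_e proportional to K^(1 - |o_e|)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Event:
    """One reaction channel: state change `delta` at rate c * prod X^orders."""

    delta: np.ndarray
    coeff: float
    orders: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.int64)
        self.orders = np.asarray(self.orders, dtype=np.int64)
        if self.coeff < 0:
            raise ValueError("rate coefficient must be nonnegative")
        if np.any(self.orders < 0):
            raise ValueError("reactant orders must be nonnegative")

    def rate(self, x: np.ndarray) -> float:
        return float(self.coeff * np.prod(np.asarray(x, dtype=float) ** self.orders))


@dataclass
class CTMCModel:
    """A mass-action population CTMC with a system-size parameter.

    Parameters
    ----------
    events : list of Event
    scale : float
        System size (N for the epidemic models, K for the within-host model).
    x0 : (d,) int array
        Initial counts.
    species : optional list of state-variable names, for reporting.
    """

    events: list[Event]
    scale: float
    x0: np.ndarray
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.int64)
        if np.any(self.x0 < 0):
            raise ValueError("initial counts must be nonnegative")
        d = self.x0.shape[0]
        for e in self.events:
            if e.delta.shape != (d,) or e.orders.shape != (d,):
                raise ValueError("event dimension mismatch")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def state_dim(self) -> int:
        return int(self.x0.shape[0])

    def rates(self, x: np.ndarray) -> np.ndarray:
        return np.array([e.rate(x) for e in self.events])

    # arrays consumed by the jitted SSA kernel
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        deltas = np.stack([e.delta for e in self.events]).astype(np.int64)
        coeffs = np.array([e.coeff for e in self.events], dtype=float)
        orders = np.stack([e.orders for e in self.events]).astype(np.int64)
        return deltas, coeffs, orders

    def density_drift(self, x: np.ndarray) -> np.ndarray:
        """Right-hand side of the fluid-limit ODE for the density x = X / K."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        K = self.scale
        for e in self.events:
            theta = e.coeff * K ** (int(e.orders.sum()) - 1)
            out += e.delta * (theta * np.prod(x**e.orders))
        return out

    def density_coefficients(self) -> np.ndarray:
        """Density-scale rate constants theta_e = c_e * K^(|o_e| - 1).

        For a density-dependent model these are O(1) numbers independent of
        the system size (e.g. the transmission rate beta itself rather than
        beta / N); they parameterise the fluid-limit ODE.
        """
        K = self.scale
        return np.array([e.coeff * K ** (int(e.orders.sum()) - 1) for e in self.events])
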