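# timeshifts

Random time-shift distributions for stochastic population models.

## The problem

Population processes that start from a handful of individuals — an index
case seeding an epidemic, a few virions infecting a host, an invading
species — go through an early window of strong demographic noise before
settling into exponential growth. In a large system this early noise does
not average away: it survives on the macroscale as a random *translation of
the time axis*. Every surviving stochastic path eventually hugs the
deterministic (fluid-limit) trajectory, but each with its own offset, which
is why, for example, the peak of an epidemic is random even when its height
is not.

For a supercritical multitype Markov branching process Z(t) with growth
matrix Ω, Malthusian parameter λ (the dominant eigenvalue of Ω) and Perron
eigenvectors **u**, **v** (normalised **u**·**1** = 1, **u**·**v** = 1), the
rescaled process e^(−λt) Z(t) converges almost surely to W **v**, where W is
a scalar random variable with an atom at 0 of mass q\* (ultimate
extinction) and a continuous part otherwise. Matching the stochastic and
mean solutions gives the time-shift

τ = λ⁻¹ log( W / E[W] ),  E[W] = **z₀**·**u**ᵀ,

so that the deterministic solution evaluated at t + τ approximates a
stochastic path. Everything therefore reduces to computing the law of W,
which this package does in two ways:

* **PE (probability estimation).** The Laplace–Stieltjes transform
  φᵢ(θ) = E[e^(−θWᵢ)] is evaluated anywhere in ℂ by combining (i) a Taylor
  expansion in the moments E[Wᵢᵏ] — computed exactly by a recursive linear
  system derived from the progeny generating functions — valid on a disc
  |θ| ≤ L(n, ε) with a provable error bound, and (ii) the functional
  equation φ(θ) = f̃(φ(θ e^(−λh))) of the h-step embedded process, whose
  generating function f̃ solves the Kolmogorov backward ODEs. The CDF of W
  is then recovered by Abate–Whitt numerical inversion of φ(θ)/θ.
* **MM (moment matching).** A generalised gamma distribution
  GG(β, α₁, α₂) is fitted to the first five moments of
  W\* = W | W > 0 by standardised least squares; its time-shift density is
  closed-form and sampling is exact.

Both routes support continuous- and discrete-time multitype processes whose
progeny generating functions are in the death / linear / quadratic family
(ν, α, β-splitting rates) — which covers mass-action population models —
and arbitrary initial count vectors z₀.

Intended users: modellers in epidemiology and within-host viral dynamics
who want stochastic-looking macroscopic ensembles (or early-noise
quantification) without paying for full Gillespie simulation of a large
system.

## Worked example

```python
import numpy as np
from timeshifts import WDistribution, TimeShiftDistribution, fixtures

bp, ctmc = fixtures.seir(beta=0.56, sigma=0.5, gamma=0.33)
wd = WDistribution(bp, z0=[1, 0])        # one exposed individual
print(wd.lam, wd.q_star)                 # 0.120934  0.589286
dist = TimeShiftDistribution(wd)
taus = dist.sample(20000, np.random.default_rng(1))
print(np.quantile(taus, [0.05, 0.5, 0.95]))
```

prints

```
0.1209337645642416 0.5892857142856709
[-17.08  4.35  16.38]
```

meaning: the epidemic grows at rate λ ≈ 0.121/day, 58.9 % of introductions
die out, and among major outbreaks the macroscopic curve typically runs
4.4 days ahead of the deterministic prediction, with a 90 % band from 17
days behind to 16 days ahead — the long left tail is slow-igniting
epidemics. The scripts in `examples/` walk through each capability (exact
SIR validation, hybrid one-ODE-solve ensembles, the six-state within-host
model reduced to a three-type branching process, and validation against
exact Gillespie simulation) and print interpreted output.

A thin CLI mirrors the library (`timeshifts compute-w | fit-mm |
sample-tau | hybrid-ensemble | validate`) over YAML model-spec files; see
`timeshifts --help`.

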