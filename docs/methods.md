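# Methods

This note records the mathematical model the package implements, the
numerical choices behind it, and what the bundled tests do and do not
establish.

## Model class

A continuous-time multitype Markov branching process (CT-MBP) on m types is
specified by three nonnegative rate arrays:

* ν_i — type i dies leaving nothing;
* α_ij (j ≠ i) — type i dies leaving one type j;
* β_ikl (k ≤ l) — type i dies leaving one type k and one type l.

The total event rate of a type-i individual is a_i = ν_i + Σα_ij + Σβ_ikl
and its progeny generating function is the quadratic polynomial
f_i(s) = (ν_i + Σ α_ij s_j + Σ β_ikl s_k s_l)/a_i. Builders normalise
quadratic input given in either index order into the canonical k ≤ l slot.
In the discrete-time variant the same arrays hold offspring probabilities
(summing to one per type) and time advances in unit steps. The quadratic
family covers mass-action population models linearised about a
small-infection state; more general offspring laws (higher-order
polynomials, parametric distributions) are out of scope.

The growth matrix is Ω_ij = α_ij + Σ_{k≤l} β_ikl(δ_jk + δ_jl) − a_i δ_ij
(mean offspring matrix M without the −a_iδ_ij term in discrete time).
Supercriticality (λ > 0, resp. ρ > 1) is enforced before any W
computation; irreducibility is checked as strong connectivity of the
offspring digraph and produces a warning, not an error, when violated,
since the Perron normalisation may still go through.

Three fixture models ship with the package: SIR (β, γ) = (0.95, 0.5); SEIR
(β, σ, γ) = (0.56, 0.5, 0.33) with types (E, I); and a six-state
within-host innate-response model whose branching reduction keeps
(E, I, V), with cell carrying capacity K = U₀ = 8·10⁷ and the published
kinetic constants as defaults. In the innate model the eclipse-phase
lifetime rate is a₁ = σ + η: both exit channels (progression at σ, death at
η) end the lifetime, and f₁(1) = 1 forces the sum. Each fixture carries the
matching density-dependent CTMC (stoichiometries plus mass-action rate
monomials), which drives both exact simulation and the fluid-limit ODE.

## Moments of W

E[W_i] = u_i. Higher conditional moments solve, order by order, the linear
system obtained by differentiating the MGF functional equation n times: the
order-n system has matrix rows e_i − Σ α_ij/(a_i + nλ) e_j −
Σ β_ikl/(a_i + nλ)(e_k + e_l) and right-hand sides that binomially convolve
lower-order moments. Systems are solved densely (LU) and sequentially; one
extra order (n + 1) is always computed because the Taylor error bound needs
it. Binomial coefficients switch from exact integers to log-gamma floats
above n = 60. Moments for an arbitrary initial count vector follow by
binomial convolution of the per-copy moment sequences (equivalent to the
multinomial expansion over integer partitions, which the tests verify by
brute-force enumeration at small sizes). Conditioning on non-extinction
divides moments k ≥ 1 by 1 − q*, where q is the minimal fixed point of
f(q) = q, found by monotone iteration from 0 (sup-norm tolerance 1e−14,
capped at 10⁶ iterations).

## LST evaluation

Inside the disc |θ| ≤ L(n, ε) = ((n+1)! ε / γ)^(1/(n+1)), with
γ = max_i E[W_i^(n+1)], the degree-n Taylor polynomial has absolute error
≤ ε for every type. Outside, the functional equation of the h-step
embedded process shrinks the argument: φ(θ) = f̃(φ(θ e^(−λh))), applied κ
times until the argument lands in the disc. The embedded generating
function f̃(s) = F(s, h) solves the backward system dF_i/dt =
a_i(f_i(F) − F_i), F(s, 0) = s; because this flow is a semigroup, κ
applications equal one integration over [0, κh], which is what the
evaluator does — batched over evaluation points by rescaling each point's
horizon onto [0, 1], so a whole inversion grid costs one adaptive solve
(RK45, rtol 1e−10 / atol 1e−12, complex state). A literal κ-step iterator
is also exposed and tested against the fused integration. Discrete-time
models use f̃ = f with shrink factor ρ⁻¹ and no ODE work. Defaults: n = 30
moments, h = 0.1, ε = 1e−6.

κ is only lower-bounded by log(|θ|/L)/(λh); the implementation deliberately
shrinks further, to an effective radius L·e^(−λh·margin). The margin is set
from the inversion weights (next section): each extra shrink step multiplies
the Taylor residual by e^(−(n+1)λh), and margin = ⌈log‖η‖₁ / ((n+1)λh)⌉
keeps the weight-amplified residual at the ε level. This is why the
package's CDF reconstruction errors come out several orders below the
minimal-κ variant of the same algorithm.

## Inversion and densities (PE route)

CDF values are recovered with the Abate–Whitt framework: G(w) =
Σ_k Re[(η_k/β_k) φ(β_k/w)] with the Euler nodes β_k = M ln10/6 + iπk and
binomially smoothed alternating weights, M odd. The Euler family's
discretisation error decays like 10^(−M/3); the default M = 31 gives
~1e−10 on smooth closed-form pairs, the same accuracy class as the
order-21 concentrated-matrix-exponential (CME) coefficient set used in the
original presentation of this pipeline. The CME coefficients are published
numerical data (the output of a matrix-exponential concentration
optimisation) rather than a formula, so this package implements the
closed-form Euler member of the same framework and matches its accuracy by
order rather than shipping foreign coefficients. The atom q* is attached at
w = 0 after inversion; raw (unclipped) values are available for error
studies, clipped-and-isotonic values feed the sampler.

The conditional density of W* is computed two ways, which agree to ~1e−6
on the fixtures and serve as mutual checks: direct inversion of the
continuous part's transform φ(θ) − q*, and the analytic w-derivative of the
inversion sum, which needs φ′(θ); φ′ is computed exactly by integrating the
variational (linearised backward-flow) equations alongside φ — the same
derivative forward-mode automatic differentiation would produce, without
an AD dependency. Sampling of W* is inverse-CDF on a monotone PCHIP
interpolant of the conditional CDF over a grid covering quantiles 1e−4 to
1 − 1e−4 (samples are drawn from that quantile range, so the extreme
1e−4 tails are truncated — negligible for the moment and KS checks the
package makes, but not suitable for extreme-tail studies).

## Moment matching (MM route)

W* is approximated by a generalised gamma GG(β, α₁, α₂) with density
∝ w^(α₁−1) exp(−(w/β)^α₂) and k-th moment β^k Γ((α₁+k)/α₂)/Γ(α₁/α₂),
fitted to the first five W* moments. Because the moments span orders of
magnitude, each is standardised to mantissa/exponent form c_k·10^(η_k)
with c_k ∈ [1, 10) — the standard scientific mantissa; the loss is the sum
of squared mantissa differences. Optimisation is multi-start L-BFGS-B on
log-parameters (positivity by construction), started at the exponential
point (β, 1, 1), the gamma method-of-moments point, and a stretched-tail
point, with a Nelder–Mead polish when the loss stays above 1e−12. For
models where the family is exact (SIR: exponential) the fit reaches loss
~1e−25 and machine-precision parameter recovery; for SEIR the family's
least-squares floor is ~1.7e−8 (relative moment errors ~1e−4), which is a
property of the family, not the optimiser — confirmed by an independent
Levenberg–Marquardt solve. The time-shift density under the surrogate is
closed-form, and sampling uses the exact transformation
β·X^(1/α₂), X ~ Gamma(α₁/α₂, 1).

## Time-shifts and hybrid trajectories

τ = λ⁻¹ log(W/μ_W) with μ_W = z₀·uᵀ. Sign convention: a path with W above
its mean runs ahead of the deterministic curve, τ > 0, and the shifted
deterministic solution ζ(t + τ) approximates it; the empirical estimator
τ̂ = t_det − t_sim (deterministic minus simulated threshold-crossing time)
uses the same orientation. The deterministic trajectory integrates the
fluid-limit ODE built from the CTMC's mass-action events (LSODA, dense
output); evaluating a shifted replicate at t + τ < 0 uses an exact
backward integration from the initial condition. Two caveats are inherent
and documented rather than hidden: (i) the backward flow of an initial
condition that is off the unstable manifold excites the decaying modes in
reverse, so backward extensions are only meaningful over modest horizons
(and can produce small negative densities — they are the exact flow, not
population states); (ii) for the same reason threshold-crossing detection
scans only the forward trajectory. The peak time is located by bounded
golden-section refinement of the dense interpolant. A hybrid ensemble of
any size costs exactly one ODE solve (asserted by a solver-call counter).

## Simulation and validation

Exact Gillespie simulation drives all distributional validation. Two
implementations: a plain-Python event loop that records full paths
(reference; small systems), and a numba-compiled kernel over the
mass-action arrays (stoichiometry, coefficient, reactant orders) for large
ensembles, with stopping on threshold crossing, extinction of designated
coordinates, a population cap (used when only survival matters: residual
extinction risk from a population of 1000 is of order q^1000), or a time
horizon. Empirical W samples divide each coordinate of e^(−λt)Z(t) by v_i
and average — every coordinate estimates the same scalar W. Empirical
time-shifts condition on survival by discarding extinct replicates and
redrawing (tested equivalent to post-hoc filtering).

Problem sizes in the shipped tests and the acceptance script were chosen to
make statistical bands decisive at interactive runtimes: 2000 surviving
SEIR runs at N = 10⁵ for the KS comparison (the KS band at that size is
~0.03, against a 0.05 criterion), 3·10⁴ branching-process runs for the
exponential-limit KS check, and binomial 99% bands for extinction
fractions. The within-host model is exercised as a smoke validation
(density normalisation, crossing-time range, extinction fraction) at
reduced replicates.

## What the synthetic setting does and does not show

All validation inputs are generated by the package's own fixtures: exact
mass-action CTMCs and their branching linearisations. Passing tests
therefore establish the numerical correctness of the pipeline (moments,
transforms, inversion, fitting, simulation estimators agree with closed
forms and with each other), and the *internal* consistency of the
time-shift theory at finite N for the models bundled. They do not speak
to model misspecification on real data: a real epidemic or infection has
non-exponential stage durations, time-varying rates and observation noise,
none of which is represented here. The branching approximation itself
degrades when the initial state is not small relative to N, and the
time-shift construction assumes the system eventually tracks the
deterministic curve — both limits inherited from the theory, visible in the
growing (but still modest) KS distances at N = 10³–10⁴.

## Numerical edge cases

* Degenerate inputs rejected with specific errors: zero lifetime rates,
  negative rates, z₀ = 0, subcritical models (SubcriticalError), moment
  requests beyond the computed order, w ≤ 0 density queries, q* = 1.
* θ on the disc boundary counts as inside; κ overflow (astronomically
  large |θ|) raises rather than looping.
* Mantissa standardisation guards the decade boundaries of floating-point
  log10.
* Extinction-probability iteration distinguishes the minimal root from the
  trivial root at 1 by starting at 0 (monotone convergence).
* Eigen-solver requires a real, simple dominant eigenvalue with
  positive-scalable eigenvectors and fails loudly otherwise.
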