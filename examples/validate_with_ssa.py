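"""Validate the computed time-shift law against exact Gillespie simulation.

For the SEIR model at N = 1e5, tau is estimated empirically as the
difference between the deterministic and simulated first times at which
the infectious count reaches 5% of the population, over surviving runs.
"""

import numpy as np
from scipy.stats import kstest

from timeshifts import TimeShiftDistribution, WDistribution, deterministic_solution, fixtures
from timeshifts.simulate import empirical_timeshift

N = 10**5
bp, ctmc = fixtures.seir(N=N)
wd = WDistribution(bp, z0=[1, 0])
dist = TimeShiftDistribution(wd)

traj = deterministic_solution(ctmc, (0.0, 400.0))
taus, n_ext, n_tot = empirical_timeshift(
    ctmc, traj, coord=2, reps=500, rng=np.random.default_rng(11),
    threshold_frac=0.05, absorb_coords=[1, 2],
)

ks = kstest(taus, lambda x: dist.cdf(np.atleast_1d(x))).statistic
print(f"surviving runs: {len(taus)} of {n_tot} ({n_ext} extinct)")
print(f"observed extinction fraction {n_ext / n_tot:.4f} vs q* = {wd.q_star:.4f}")
print(f"KS distance between empirical tau and the computed tau* law: {ks:.4f}")
print("values below ~0.06 at this sample size are consistent with agreement.")
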