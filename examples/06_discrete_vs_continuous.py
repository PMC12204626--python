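"""Can counts distinguish a two-state switch from continuous adaptation?

The discrete model (sensitive <-> resistant with drug-dependent switching)
has mean counts that a continuous homogeneous model with quadratic
adaptation velocity reproduces exactly.  Differences appear only in higher
moments of the count distribution.
"""

import dataclasses

import numpy as np

from phenoadapt import cme, pde
from phenoadapt.model_core import TreatmentSchedule

dp = cme.DiscreteModelParams()  # drug-on: r01=1, r10=0.01, lam0=-0.3, lam1=0.1
sched = TreatmentSchedule.continuous(True)
times = np.array([0.0, 1.0, 3.0, 5.0, 7.0])

ode_mean = cme.discrete_mean_counts(dp, sched, (10.0, 0.0), times).sum(axis=1)
spec = dataclasses.replace(cme.continuous_equivalent(dp), schedule=sched)
sol = pde.solve_structured_density(spec, (10.0, 0.0, 0.0), times)
A, B, C = cme.discrete_mean_phenotype_coeffs(dp, 1)
print(f"equivalent quadratic velocity: dx/dt = {A:.2f} {B:+.2f} x {C:+.2f} x^2")

init = np.zeros((11, 1)); init[10, 0] = 1.0
dist_d, _ = cme.solve_discrete_joint_cme(dp, sched, init, times, cap0=60, cap1=130)
sol_fine = pde.solve_structured_density(spec, (10.0, 0.0, 0.0), pde.default_times(7.0))
fp, fd = pde.rate_interpolants(sol_fine)
q0 = np.zeros(11); q0[10] = 1.0
dist_c = cme.solve_count_cme(fp, fd, q0, times, n_max=256)

print("\n t    mean(discrete)  mean(continuous)   var(discrete)  var(continuous)")
for i, t in enumerate(times):
    print(
        f" {t:3.0f}   {cme.distribution_mean(dist_d.q[i]):13.4f}"
        f"  {sol.n_mean[i]:15.4f}"
        f"   {cme.distribution_variance(dist_d.q[i]):12.4f}"
        f"  {cme.distribution_variance(dist_c.q[i]):14.4f}"
    )
print(
    "\nMeans coincide to solver precision at every time — average counts cannot"
    "\nseparate the hypotheses.  The discrete model's variance runs higher"
    "\n(switching adds demographic noise), so only moments beyond the mean,"
    "\nor single-cell marker data, can distinguish the two pictures."
)
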