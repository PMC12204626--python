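"""The stationary phenotype law that seeds every experiment.

Phenotypes of an untreated, growth-neutral population settle into the
Ornstein-Uhlenbeck stationary law N(0, beta^2 / 2 nu); the closed form is
checked against a long equilibrium simulation.
"""

import numpy as np

from phenoadapt import ibm
from phenoadapt.model_core import (
    DiffusionParam, GrowthParams, ModelSpec, TreatmentSchedule,
    VelocityParams, stationary_phenotype_params,
)

nu, beta = 0.4, 0.05
mean, sd_closed = stationary_phenotype_params(
    0, VelocityParams(form="OU", nu=nu), DiffusionParam(beta)
)
print(f"closed form: mean {mean:.3f}, sd = beta/sqrt(2 nu) = {sd_closed:.4f}")

spec = ModelSpec(
    growth=GrowthParams(0, 0, 0, 0),  # growth disabled: pure phenotype dynamics
    schedule=TreatmentSchedule.continuous(False),
)
rng = ibm.child_rng(1)
traj = ibm.simulate(
    ibm.Population(np.zeros(2000)), spec, 12.0, rng,
    snapshot_times=[12.0], keep_phenotypes=True, log_events=False,
)
x = traj.phenotype_snapshots[12.0]
print(f"simulation  : mean {x.mean():+.4f}, sd {x.std():.4f}  (2000 cells, 12 d)")
print(
    "\nThe sd ~ 0.056 quantifies the cell-to-cell phenotype heterogeneity that"
    "\nthe diffusion amplitude beta = 0.05 induces around the sensitive state."
)
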