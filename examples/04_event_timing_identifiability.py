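"""Heterogeneity becomes identifiable when event timings are observed.

Simulates an assay started with 3,000 cells under continuous drug, records
every proliferation and death event in 0.035-day bins, and fits the Poisson
event-count likelihood.  Because only a heterogeneous population can
proliferate and die at the same instant, the diffusivity beta is now pinned
down (contrast with terminal counts alone).
"""

from phenoadapt import synthetic_data as sd
from phenoadapt.inference import PriorBox, maximize_loglik
from phenoadapt.likelihoods import SolverOptions, ThetaVector, loglik_event_timings
from phenoadapt.model_core import ModelSpec

TRUTH = {"gamma1": 0.15, "gamma2": -0.3, "gamma3": 0.1, "gamma4": 0.1,
         "nu": 0.4, "beta": 0.05}

events = sd.generate_event_data(ModelSpec(), rng_seed=5, n0_total=3000)
df = events.df
mid = df[(df.bin_start > 3.0) & (df.bin_end < 4.0)]
print(f"{len(df)} bins; births {df.n_prolif_events.sum()}, deaths {df.n_death_events.sum()}")
print(f"around the proliferation-death transition (3-4 d): "
      f"{mid.n_prolif_events.sum()} births and {mid.n_death_events.sum()} deaths coexist")

theta = ThetaVector(
    free_names=("gamma2", "gamma4", "nu", "beta"),
    fixed={"gamma1": 0.15, "gamma3": 0.1},
)
mle, ll = maximize_loglik(
    lambda p: loglik_event_timings(events, p, opts=SolverOptions.fast()),
    theta, PriorBox(), maxfun=250, init=TRUTH,
)
for name in theta.free_names:
    print(f"  {name:7s}  MAP {mle[name]:+.4f}   truth {TRUTH[name]:+.3f}")
print(
    "\nbeta lands within a small factor of its true 0.05: the overlap of birth"
    "\nand death events in time carries the heterogeneity signal that terminal"
    "\ncell counts wash out."
)
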