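"""Fit the count-CME likelihood to a (scaled-down) proliferation-assay study.

Generates a reduced four-condition dataset (24 replicates instead of 48),
then maximises the master-equation likelihood over the growth rates and the
adaptation speed.  The diffusivity beta is left free too: note how poorly
it is pinned down by count data.
"""

from phenoadapt import synthetic_data as sd
from phenoadapt.datasets import Condition
from phenoadapt.inference import PriorBox, maximize_loglik
from phenoadapt.likelihoods import SolverOptions, ThetaVector, loglik_counts
from phenoadapt.model_core import ModelSpec

TRUTH = {"gamma1": 0.15, "gamma2": -0.3, "gamma3": 0.1, "gamma4": 0.1,
         "nu": 0.4, "beta": 0.05}

design = sd.ExperimentDesign(
    conditions=(
        Condition("sensitive_drug_off", 0, "drug_off"),
        Condition("sensitive_drug_on", 0, "drug_on"),
        Condition("resistant_drug_off", 1, "drug_off"),
        Condition("resistant_drug_on", 1, "drug_on"),
    ),
    times=(1.0, 3.0, 5.0, 7.0),
    replicates=24,
)
data = sd.generate_count_data(design, ModelSpec(), rng_seed=1)
print(f"dataset: {len(data.df)} terminal counts across 4 conditions x 4 times")

theta = ThetaVector(free_names=("gamma1", "gamma2", "gamma3", "gamma4", "nu", "beta"))
mle, ll = maximize_loglik(
    lambda p: loglik_counts(data, p, opts=SolverOptions.fast()),
    theta, PriorBox(), maxfun=300, init=TRUTH,
)
print(f"log-likelihood at the MAP: {ll:.2f}")
for name in theta.free_names:
    print(f"  {name:7s}  MAP {mle[name]:+.4f}   truth {TRUTH[name]:+.3f}")
print(
    "\nGrowth rates and the adaptation speed land near their true values,"
    "\nwith scatter set by this reduced design (half the replicates of the full study);"
    "\nthe beta estimate is essentially arbitrary below its true value —"
    "\ncount data bound the heterogeneity from above only."
)
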