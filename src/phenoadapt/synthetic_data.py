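"""Synthetic-data generators reproducing the study's experimental designs.

Three modalities are generated, all by simulating the individual-based
model:

* count data — four conditions (sensitive/resistant start, drug on/off),
  termination times {1, 3, 5, 7} d, M = 48 replicate wells per condition and
  time (two 96-well plates per termination time), each well seeded with
  ~1000 cells of which a Binomial field-of-view fraction is observed;
* event-timing data — one large assay started with 10,000 cells under
  continuous drug, with every proliferation and death event binned into 200
  intervals of width 0.035 d over 7 d;
* marker data — per-cell phenotype-marker values M_i = x_i + eps at sampling
  times {1, 3, 5, 7} d from drug-treated, initially sensitive wells, with
  Gaussian or translated-Gamma measurement noise.

Every replicate well is an independent realisation of the IBM.  Wells
sharing a (condition, termination-time) cell are simulated as one pooled
batch driven by its own child generator, so datasets are deterministic
given (design, parameters, root seed) and independent across batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .datasets import Condition, CountDataset, EventDataset, MarkerDataset
from .ibm import child_rng, simulate, simulate_batch, DEFAULT_DT
from .model_core import ModelSpec, TreatmentSchedule, stationary_phenotype_params

__all__ = [
    "DEFAULT_FOV_PROB",
    "ExperimentDesign",
    "MarkerNoiseParams",
    "default_design",
    "marker_design",
    "generate_count_data",
    "generate_event_data",
    "generate_marker_data",
    "sample_marker_noise",
]

# imaged window 817 x 614 um in a 9 mm (4500 um radius) well
DEFAULT_FOV_PROB = 817.0 * 614.0 / (4500.0 ** 2 * math.pi)


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate layout: conditions x termination times x replicates."""

    conditions: Tuple[Condition, ...]
    times: Tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    replicates: int = 48
    n_well: int = 1000
    fov_prob: float = DEFAULT_FOV_PROB

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(t <= 0 for t in self.times):
            raise ValueError("termination times must be positive")
        if not 0.0 < self.fov_prob <= 1.0:
            raise ValueError("fov_prob must lie in (0, 1]")

    @property
    def n_records(self) -> int:
        return len(self.conditions) * len(self.times) * self.replicates

    def to_dict(self) -> dict:
        return {
            "conditions": [asdict(c) for c in self.conditions],
            "times": list(self.times),
            "replicates": self.replicates,
            "n_well": self.n_well,
            "fov_prob": self.fov_prob,
        }


@dataclass(frozen=True)
class MarkerNoiseParams:
    """Marker measurement-noise law: sd sigma, skewness omega.

    omega = 0 is Gaussian; otherwise a translated Gamma with zero mean,
    standard deviation sigma and skewness omega (shape 4/omega**2, scale
    sigma |omega| / 2, location shifted to zero mean, mirrored for
    omega < 0), which tends to the Gaussian as omega -> 0.
    """

    sigma: float = 0.1
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not math.isfinite(self.omega):
            raise ValueError("omega must be finite")


def default_design() -> ExperimentDesign:
    """The four-condition count-data design: 2 plates per termination time."""
    conditions = (
        Condition("sensitive_drug_off", 0, "drug_off"),
        Condition("sensitive_drug_on", 0, "drug_on"),
        Condition("resistant_drug_off", 1, "drug_off"),
        Condition("resistant_drug_on", 1, "drug_on"),
    )
    return ExperimentDesign(conditions=conditions)


def marker_design() -> ExperimentDesign:
    """Marker sampling design: drug-treated sensitive wells only."""
    return ExperimentDesign(conditions=(Condition("sensitive_drug_on", 0, "drug_on"),))


def _initial_phenotypes_batch(
    design: ExperimentDesign, P: int, spec: ModelSpec, rng: np.random.Generator
) -> List[np.ndarray]:
    if spec.diffusion.beta == 0.0:
        mean, sd = float(P), 0.0
    elif spec.velocity.form == "OU":
        mean, sd = stationary_phenotype_params(P, spec.velocity, spec.diffusion)
    else:
        # no closed stationary form: seed at the starting state with an
        # OU-like width set by the diffusion amplitude
        mean, sd = float(P), spec.diffusion.beta
    n0s = rng.binomial(design.n_well, design.fov_prob, size=design.replicates)
    return [
        mean + sd * rng.standard_normal(n) if sd > 0 else np.full(n, float(mean))
        for n in n0s
    ]


def generate_count_data(
    design: ExperimentDesign,
    spec: ModelSpec,
    rng_seed: int,
    dt: float = DEFAULT_DT,
    schedules: Optional[Dict[str, TreatmentSchedule]] = None,
) -> CountDataset:
    """Simulate the count-data design; one IBM realisation per well."""
    from .datasets import DEFAULT_SCHEDULES
    import dataclasses as _dc

    schedules = dict(DEFAULT_SCHEDULES) | (schedules or {})
    rows = []
    batch = 0
    for cond in design.conditions:
        cond_spec = _dc.replace(spec, schedule=cond.schedule(schedules))
        for t in design.times:
            rng = child_rng(rng_seed, batch)
            batch += 1
            inits = _initial_phenotypes_batch(design, cond.P, cond_spec, rng)
            _, counts, _ = simulate_batch(inits, cond_spec, t, rng, dt=dt)
            for k, n in enumerate(counts[-1]):
                rows.append(
                    (cond.condition_id, cond.P, cond.schedule_id, t, k, int(n))
                )
    df = pd.DataFrame(
        rows,
        columns=["condition_id", "P", "schedule_id", "t_days", "replicate", "count"],
    )
    meta = {
        "modality": "counts",
        "design": design.to_dict(),
        "theta": spec.to_dict(),
        "rng_seed": int(rng_seed),
        "dt": dt,
        "package_version": __version__,
    }
    return CountDataset(df=df, metadata=meta, schedules=schedules)


def generate_event_data(
    spec: ModelSpec,
    rng_seed: int,
    n0_total: int = 10000,
    delta_t: float = 0.035,
    t_end: float = 7.0,
    P: int = 0,
    dt: float = DEFAULT_DT,
) -> EventDataset:
    """Simulate one large assay and bin its exact event timings.

    The default reproduces the event-timing design: 10,000 initially
    sensitive cells under continuous drug, 200 bins of width 0.035 d.
    """
    n_bins = int(round(t_end / delta_t))
    edges = np.linspace(0.0, t_end, n_bins + 1)
    rng = child_rng(rng_seed, 0)
    mean, sd = stationary_phenotype_params(P, spec.velocity, spec.diffusion)
    x0 = mean + sd * rng.standard_normal(n0_total) if sd > 0 else np.full(n0_total, mean)
    from .ibm import Population

    traj = simulate(
        Population(x0),
        spec,
        t_end,
        rng,
        dt=dt,
        snapshot_times=edges[:-1],
        log_events=True,
    )
    ev_t = np.asarray(traj.events.times)
    is_birth = np.asarray([k == "proliferation" for k in traj.events.types])
    # events at exactly a bin edge belong to the earlier bin (they occur at
    # the end of the step that closes it)
    which = np.clip(np.ceil(ev_t / delta_t - 1e-9).astype(int) - 1, 0, n_bins - 1)
    births = np.bincount(which[is_birth], minlength=n_bins)
    deaths = np.bincount(which[~is_birth], minlength=n_bins)
    n_start = traj.counts  # counts at bin starts (snapshot times = left edges)
    df = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_at_start": n_start,
            "n_prolif_events": births,
            "n_death_events": deaths,
        }
    )
    meta = {
        "modality": "events",
        "theta": spec.to_dict(),
        "rng_seed": int(rng_seed),
        "n0_total": n0_total,
        "delta_t": delta_t,
        "t_end": t_end,
        "P": P,
        "dt": dt,
        "package_version": __version__,
    }
    return EventDataset(df=df, metadata=meta)


def sample_marker_noise(
    noise: MarkerNoiseParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw measurement-noise values from the configured law."""
    if noise.omega == 0.0:
        return noise.sigma * rng.standard_normal(size)
    k = 4.0 / noise.omega ** 2
    s = noise.sigma * abs(noise.omega) / 2.0
    draws = rng.gamma(k, s, size=size) - k * s
    return draws if noise.omega > 0 else -draws


def generate_marker_data(
    design: ExperimentDesign,
    spec: ModelSpec,
    noise: MarkerNoiseParams,
    rng_seed: int,
    dt: float = DEFAULT_DT,
) -> MarkerDataset:
    """Simulate marker measurements: every cell alive at the sampling time in
    each replicate well contributes M_i = x_i + eps."""
    import dataclasses as _dc
    from .datasets import DEFAULT_SCHEDULES

    rows = []
    batch = 0
    cell_id = 0
    for cond in design.conditions:
        cond_spec = _dc.replace(spec, schedule=cond.schedule(DEFAULT_SCHEDULES))
        for t in design.times:
            rng = child_rng(rng_seed, batch)
            batch += 1
            inits = _initial_phenotypes_batch(design, cond.P, cond_spec, rng)
            _, _, phen = simulate_batch(
                inits, cond_spec, t, rng, dt=dt, keep_phenotypes=True
            )
            _, x = phen[t]
            m = x + sample_marker_noise(noise, x.size, rng)
            for val in m:
                rows.append((t, cell_id, float(val)))
                cell_id += 1
    df = pd.DataFrame(rows, columns=["t_days", "cell_id", "marker_value"])
    meta = {
        "modality": "marker",
        "design": design.to_dict(),
        "theta": spec.to_dict(),
        "noise": {"sigma": noise.sigma, "omega": noise.omega},
        "rng_seed": int(rng_seed),
        "dt": dt,
        "package_version": __version__,
    }
    return MarkerDataset(df=df, metadata=meta)
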