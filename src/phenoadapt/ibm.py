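"""Stochastic individual-based simulator.

Each cell carries a phenotype index evolving by Euler-Maruyama steps of the
adaptation SDE; proliferation and death are phenotype-dependent Poisson
processes routed by the sign of the net growth rate (positive rates are pure
proliferation, negative pure death).  Daughters inherit the parent phenotype
exactly at division.  Extinction is absorbing: there is no migration into
the field of view.

Within a step the phenotype update precedes the event draws, and event
probabilities use the exponential form 1 - exp(-rate * dt) so they never
exceed one.  A cell proliferates or dies in a step, never both (the growth
rate routes to exactly one channel).

Seeding: a root seed expands into per-replicate child seeds through
``numpy``'s ``SeedSequence`` spawn keys, so replicate sets are reproducible
and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    ModelSpec,
    drug_indicator,
    growth_rate,
    stationary_phenotype_params,
    velocity,
)

__all__ = [
    "Population",
    "EventLog",
    "IBMTrajectory",
    "sample_initial_population",
    "step_population",
    "simulate",
    "simulate_batch",
    "child_rng",
]

DEFAULT_DT = 1e-3  # days; well below 1/nu = 2.5 d and 1/max|lambda| ~ 3.3 d


def child_rng(root_seed: int, index: int = 0) -> np.random.Generator:
    """Deterministic, order-independent child generator for replicate ``index``."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(index,)))


@dataclass
class Population:
    """Current phenotype state of the simulated cells."""

    phenotypes: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)

    @property
    def size(self) -> int:
        return int(self.phenotypes.size)


@dataclass
class EventLog:
    """Proliferation/death events: parallel arrays of time, type, phenotype."""

    times: List[float] = field(default_factory=list)
    types: List[str] = field(default_factory=list)  # "proliferation" | "death"
    phenotypes: List[float] = field(default_factory=list)

    def append(self, t: float, kind: str, x: float) -> None:
        self.times.append(t)
        self.types.append(kind)
        self.phenotypes.append(x)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class IBMTrajectory:
    """Snapshot times, counts, optional phenotype snapshots, and event log."""

    snapshot_times: np.ndarray
    counts: np.ndarray
    events: EventLog
    phenotype_snapshots: Optional[Dict[float, np.ndarray]] = None
    final_population: Optional[Population] = None

    def counts_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.snapshot_times, "count": self.counts}).to_csv(
            path, index=False
        )

    def events_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time": self.events.times,
                "event_type": self.events.types,
                "phenotype": self.events.phenotypes,
            }
        ).to_csv(path, index=False)

    def phenotypes_to_csv(self, path) -> None:
        """One row per cell: snapshot time and phenotype index."""
        import pandas as pd

        if self.phenotype_snapshots is None:
            raise ValueError("trajectory was simulated without phenotype snapshots")
        rows = [
            (t, x) for t, xs in sorted(self.phenotype_snapshots.items()) for x in xs
        ]
        pd.DataFrame(rows, columns=["time", "phenotype"]).to_csv(path, index=False)


def sample_initial_population(
    n_well: int,
    fov_prob: float,
    P: int,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> Population:
    """Binomial field-of-view thinning of a seeded well.

    The observed count is n0 ~ Binomial(n_well, fov_prob); phenotypes are
    drawn from the stationary law of the initial population type P.
    """
    if not 0.0 <= fov_prob <= 1.0:
        raise ValueError("fov_prob must lie in [0, 1]")
    if n_well < 0:
        raise ValueError("n_well must be nonnegative")
    n0 = int(rng.binomial(n_well, fov_prob)) if n_well > 0 else 0
    mean, sd = stationary_phenotype_params(P, spec.velocity, spec.diffusion)
    x = mean + sd * rng.standard_normal(n0) if sd > 0 else np.full(n0, mean)
    return Population(phenotypes=x, time=0.0)


def step_population(
    pop: Population,
    spec: ModelSpec,
    dt: float,
    rng: np.random.Generator,
    log: Optional[EventLog] = None,
) -> Population:
    """Advance the population by one Euler-Maruyama + event step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    tx = drug_indicator(pop.time, spec.schedule)
    x = pop.phenotypes
    n = x.size
    if n:
        v = velocity(x, tx, spec.velocity)
        x = x + v * dt
        beta = spec.diffusion.beta
        if beta > 0:
            x = x + beta * math.sqrt(dt) * rng.standard_normal(n)
        lam = np.asarray(growth_rate(x, tx, spec.growth), dtype=float)
        p_event = -np.expm1(-np.abs(lam) * dt)
        u = rng.random(n)
        fired = u < p_event
        if fired.any():
            births = fired & (lam > 0)
            deaths = fired & (lam < 0)
            t_ev = pop.time + dt
            if log is not None:
                for xi in x[births]:
                    log.append(t_ev, "proliferation", float(xi))
                for xi in x[deaths]:
                    log.append(t_ev, "death", float(xi))
            if deaths.any():
                keep = ~deaths
                new_x = np.concatenate([x[keep], x[births]])
            else:
                new_x = np.concatenate([x, x[births]]) if births.any() else x
            x = new_x
    return Population(phenotypes=x, time=pop.time + dt)


def simulate(
    pop0: Population,
    spec: ModelSpec,
    t_end: float,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    snapshot_times: Optional[Sequence[float]] = None,
    keep_phenotypes: bool = False,
    log_events: bool = True,
) -> IBMTrajectory:
    """Simulate the population to ``t_end``, recording counts at snapshots.

    Snapshot times are rounded to the step grid.  The trajectory is
    deterministic given the generator state; extinction (N = 0) is
    absorbing.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_steps = int(round(t_end / dt))
    if abs(n_steps * dt - t_end) > 1e-9:
        n_steps = int(math.ceil(t_end / dt - 1e-12))
    if snapshot_times is None:
        snapshot_times = [t_end]
    snap_steps = {}
    for t in snapshot_times:
        if not 0.0 <= t <= t_end + 1e-9:
            raise ValueError("snapshot times must lie in [0, t_end]")
        snap_steps.setdefault(min(int(round(t / dt)), n_steps), []).append(float(t))

    log = EventLog() if log_events else None
    counts: List[int] = []
    times_out: List[float] = []
    phen: Dict[float, np.ndarray] = {}

    pop = pop0

    def record(step: int) -> None:
        for t in snap_steps.get(step, ()):
            times_out.append(t)
            counts.append(pop.size)
            if keep_phenotypes:
                phen[t] = pop.phenotypes.copy()

    record(0)
    for k in range(n_steps):
        if pop.size:
            pop = step_population(pop, spec, dt, rng, log=log)
        else:
            pop = Population(phenotypes=pop.phenotypes, time=pop.time + dt)
        record(k + 1)

    order = np.argsort(times_out, kind="stable")
    return IBMTrajectory(
        snapshot_times=np.asarray(times_out)[order],
        counts=np.asarray(counts, dtype=int)[order],
        events=log if log is not None else EventLog(),
        phenotype_snapshots=phen if keep_phenotypes else None,
        final_population=pop,
    )


def simulate_batch(
    initial_phenotypes: Sequence[np.ndarray],
    spec: ModelSpec,
    t_end: float,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    snapshot_times: Optional[Sequence[float]] = None,
    keep_phenotypes: bool = False,
) -> Tuple[np.ndarray, np.ndarray, Optional[Dict[float, Tuple[np.ndarray, np.ndarray]]]]:
    """Simulate many independent replicate wells in one pooled pass.

    The replicates are statistically independent (cells never interact and
    each carries a replicate label); pooling them into one array amortises
    the per-step cost across the batch.  One generator drives the whole
    batch, so determinism is at the batch level.

    Returns ``(snapshot_times, counts, phenotypes)`` where ``counts`` has
    shape (n_snapshots, n_replicates) and ``phenotypes`` (if requested) maps
    each snapshot time to ``(replicate_ids, phenotype_values)``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    n_rep = len(initial_phenotypes)
    x = np.concatenate([np.asarray(p, dtype=float) for p in initial_phenotypes])
    rep = np.concatenate(
        [np.full(len(p), i, dtype=np.int64) for i, p in enumerate(initial_phenotypes)]
    )

    n_steps = int(math.ceil(t_end / dt - 1e-12))
    if snapshot_times is None:
        snapshot_times = [t_end]
    snap_steps: Dict[int, List[float]] = {}
    for t in snapshot_times:
        if not 0.0 <= t <= t_end + 1e-9:
            raise ValueError("snapshot times must lie in [0, t_end]")
        snap_steps.setdefault(min(int(round(t / dt)), n_steps), []).append(float(t))

    times_out: List[float] = []
    counts_out: List[np.ndarray] = []
    phen: Dict[float, Tuple[np.ndarray, np.ndarray]] = {}

    def record(step: int) -> None:
        for t in snap_steps.get(step, ()):
            times_out.append(t)
            counts_out.append(np.bincount(rep, minlength=n_rep))
            if keep_phenotypes:
                phen[t] = (rep.copy(), x.copy())

    sqrt_dt = math.sqrt(dt)
    beta = spec.diffusion.beta
    record(0)
    t = 0.0
    for k in range(n_steps):
        if x.size:
            tx = drug_indicator(t, spec.schedule)
            x = x + np.asarray(velocity(x, tx, spec.velocity)) * dt
            if beta > 0:
                x = x + beta * sqrt_dt * rng.standard_normal(x.size)
            lam = np.asarray(growth_rate(x, tx, spec.growth), dtype=float)
            fired = rng.random(x.size) < -np.expm1(-np.abs(lam) * dt)
            if fired.any():
                births = fired & (lam > 0)
                deaths = fired & (lam < 0)
                keep = ~deaths
                x = np.concatenate([x[keep], x[births]])
                rep = np.concatenate([rep[keep], rep[births]])
        t += dt
        record(k + 1)

    order = np.argsort(times_out, kind="stable")
    times_arr = np.asarray(times_out)[order]
    counts_arr = np.asarray(counts_out)[order]
    return times_arr, counts_arr, (phen if keep_phenotypes else None)
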