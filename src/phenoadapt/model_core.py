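"""Model parameterisation for drug-driven phenotypic adaptation.

A population of cells carries a continuous phenotype index ``x`` with the
convention that ``x = 0`` is the drug-sensitive equilibrium and ``x = 1`` the
drug-resistant equilibrium.  Each cell's phenotype follows the SDE

    dx = v(x, Tx) dt + beta dW,

where ``Tx`` indicates drug presence, ``v`` is the (drug-dependent)
adaptation velocity and ``beta`` sets the magnitude of random phenotype
fluctuations — the model's proxy for cell-to-cell heterogeneity.  The net
per-capita growth rate is linear in the phenotype,

    lambda(x, Tx) = gamma1 + (gamma3 - gamma1) x      (no drug),
                    gamma2 + (gamma4 - gamma2) x      (drug),

with positive values interpreted as pure proliferation and negative values as
pure death.

Noise convention
----------------
The SDE amplitude is ``beta``, so the Fokker-Planck diffusion coefficient is
``beta**2 / 2`` and the Ornstein-Uhlenbeck stationary standard deviation is
``beta / sqrt(2 nu)``.  At the default ``beta = 0.05``, ``nu = 0.4`` this
gives sd ≈ 0.0559 ≈ 0.05, the intended order of phenotypic heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np

__all__ = [
    "GrowthParams",
    "VelocityParams",
    "DiffusionParam",
    "TreatmentSchedule",
    "ModelSpec",
    "growth_rate",
    "velocity",
    "drug_indicator",
    "stationary_phenotype_params",
]


@dataclass(frozen=True)
class GrowthParams:
    """Net growth rates (per day) of the four phenotype/drug corner states.

    gamma1: sensitive (x=0), no drug.   gamma2: sensitive, drug.
    gamma3: resistant (x=1), no drug.   gamma4: resistant, drug.
    """

    gamma1: float = 0.15
    gamma2: float = -0.3
    gamma3: float = 0.1
    gamma4: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "gamma4"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class VelocityParams:
    """Adaptation-velocity family.

    form="OU": v(x, Tx) = -nu (x - Tx), mean reversion toward the
    drug-appropriate equilibrium at rate ``nu`` (per day).

    form="GENERAL": the drug-on family
    v(x, 1) = a sgn(1 - x) + (1 - x)(b + c x + d x**2), defined only in the
    adapting (drug-on) direction; a=c=d=0, b=nu recovers the OU form.

    form="QUADRATIC": drug-indexed quadratic v(x, Tx) = q0 + q1 x + q2 x**2
    with coefficients ``quad_on`` / ``quad_off``; used for the continuous
    model equivalent to the discrete two-state switch.
    """

    form: str = "OU"
    nu: float = 0.4
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    quad_on: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    quad_off: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.form not in ("OU", "GENERAL", "QUADRATIC"):
            raise ValueError(f"unknown velocity form {self.form!r}")
        if self.form == "OU" and not self.nu > 0:
            raise ValueError("OU velocity requires nu > 0")


@dataclass(frozen=True)
class DiffusionParam:
    """Phenotype-space noise amplitude (phenotype units / day**0.5)."""

    beta: float = 0.05

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Piecewise-constant drug schedule.

    ``initial_state`` is the drug indicator on [0, first switch); the
    indicator toggles at each time in ``switch_times``.  Schedules are
    right-continuous: at a switch time the post-switch state applies.
    """

    initial_state: int = 1
    switch_times: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.initial_state not in (0, 1):
            raise ValueError("initial_state must be 0 or 1")
        ts = tuple(float(t) for t in self.switch_times)
        if any(t < 0 for t in ts):
            raise ValueError("switch times must be nonnegative")
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("switch times must be strictly increasing")
        object.__setattr__(self, "switch_times", ts)

    @classmethod
    def continuous(cls, drug_on: bool = True) -> "TreatmentSchedule":
        return cls(initial_state=int(drug_on), switch_times=())

    @classmethod
    def intermittent(
        cls, period: float = 7.0, t_end: float = 28.0, drug_on_first: bool = True
    ) -> "TreatmentSchedule":
        """Alternating drug-on / drug-off periods of the given length."""
        n = int(math.floor(t_end / period))
        times = tuple(period * k for k in range(1, n + 1) if period * k < t_end)
        return cls(initial_state=int(drug_on_first), switch_times=times)

    def segments(self, t_end: float) -> list:
        """(t0, t1, tx) constant-drug integration segments covering [0, t_end]."""
        breaks = [0.0] + [t for t in self.switch_times if 0.0 < t < t_end] + [t_end]
        segs = []
        state = self.initial_state
        for k, (t0, t1) in enumerate(zip(breaks, breaks[1:])):
            segs.append((t0, t1, state))
            state = 1 - state
        return segs


@dataclass(frozen=True)
class ModelSpec:
    """Complete continuous-model parameterisation."""

    growth: GrowthParams = field(default_factory=GrowthParams)
    velocity: VelocityParams = field(default_factory=VelocityParams)
    diffusion: DiffusionParam = field(default_factory=DiffusionParam)
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)

    def to_dict(self) -> dict:
        d = {
            "growth": asdict(self.growth),
            "velocity": asdict(self.velocity),
            "diffusion": asdict(self.diffusion),
            "schedule": {
                "initial_state": self.schedule.initial_state,
                "switch_times": list(self.schedule.switch_times),
            },
        }
        d["velocity"]["quad_on"] = list(self.velocity.quad_on)
        d["velocity"]["quad_off"] = list(self.velocity.quad_off)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        vel = dict(d.get("velocity", {}))
        for key in ("quad_on", "quad_off"):
            if key in vel:
                vel[key] = tuple(vel[key])
        return cls(
            growth=GrowthParams(**d.get("growth", {})),
            velocity=VelocityParams(**vel),
            diffusion=DiffusionParam(**d.get("diffusion", {})),
            schedule=TreatmentSchedule(
                initial_state=d.get("schedule", {}).get("initial_state", 1),
                switch_times=tuple(d.get("schedule", {}).get("switch_times", ())),
            ),
        )


def growth_rate(x, tx: int, gp: GrowthParams):
    """Net per-capita growth rate lambda(x, Tx), linear in the phenotype.

    Vectorised over ``x``; the linear form extrapolates outside [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if tx not in (0, 1):
        raise ValueError("Tx must be 0 or 1")
    if tx == 0:
        out = gp.gamma1 + (gp.gamma3 - gp.gamma1) * x
    else:
        out = gp.gamma2 + (gp.gamma4 - gp.gamma2) * x
    return out if out.ndim else float(out)


def velocity(x, tx: int, vp: VelocityParams):
    """Adaptation velocity v(x, Tx) (phenotype units per day); vectorised."""
    x = np.asarray(x, dtype=float)
    if tx not in (0, 1):
        raise ValueError("Tx must be 0 or 1")
    if vp.form == "OU":
        out = -vp.nu * (x - tx)
    elif vp.form == "GENERAL":
        if tx != 1:
            raise ValueError(
                "the GENERAL velocity family is defined only for the "
                "drug-on (adapting) direction, Tx=1"
            )
        out = vp.a * np.sign(1.0 - x) + (1.0 - x) * (vp.b + vp.c * x + vp.d * x * x)
    else:  # QUADRATIC
        q0, q1, q2 = vp.quad_on if tx == 1 else vp.quad_off
        out = q0 + q1 * x + q2 * x * x
    return out if out.ndim else float(out)


def drug_indicator(t: float, schedule: TreatmentSchedule) -> int:
    """Drug indicator Tx(t); right-continuous at switch times."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    n_switches = int(np.searchsorted(np.asarray(schedule.switch_times), t, side="right"))
    return schedule.initial_state ^ (n_switches & 1)


def stationary_phenotype_params(
    P: int, vp: VelocityParams, dp: DiffusionParam
) -> Tuple[float, float]:
    """Mean and sd of the zero-net-growth stationary phenotype distribution.

    For the OU velocity the stationary law of the phenotype SDE (growth
    disabled) is Normal(P, beta**2 / (2 nu)); populations are seeded from
    this law with P = 0 (sensitive) or P = 1 (resistant).
    """
    if P not in (0, 1):
        raise ValueError("initial population type P must be 0 or 1")
    if vp.form != "OU":
        raise ValueError(
            "closed-form stationary distribution only exists for the OU "
            "velocity; equilibrate the PDE for other forms"
        )
    return float(P), dp.beta / math.sqrt(2.0 * vp.nu)
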