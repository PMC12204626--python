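"""Count-level chemical master equation, and the discrete two-state model.

The cell count N(t) of a well-mixed population with per-capita proliferation
and death rates r_prol(t), r_death(t) obeys the linear birth-death master
equation

    dq(n)/dt = (n-1) r_prol q(n-1) - n (r_prol + r_death) q(n) +
               (n+1) r_death q(n+1),

with q(n) = 0 for n < 0 and n = 0 absorbing (extinction).  The rates are
supplied by the structured-density (PDE) solution, so the CME propagates
intrinsic demographic noise exactly under the phenotype-independence
approximation.

This module also implements the standard discrete-binary alternative: two
subpopulations (sensitive X0, resistant X1) with drug-dependent switching
rates r01, r10 and net growth rates lam0, lam1, its mean ODEs, the mean
resistant-fraction ODE (a quadratic velocity), the exact joint master
equation, and the mapping onto an equivalent continuous homogeneous model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.stats import binom

from .model_core import (
    DiffusionParam,
    GrowthParams,
    ModelSpec,
    TreatmentSchedule,
    VelocityParams,
)

__all__ = [
    "CountDistribution",
    "DiscreteModelParams",
    "TruncationError",
    "binomial_initial_distribution",
    "solve_count_cme",
    "count_quantiles",
    "distribution_mean",
    "distribution_variance",
    "discrete_mean_counts",
    "discrete_mean_phenotype_coeffs",
    "solve_discrete_joint_cme",
    "continuous_equivalent",
]


class TruncationError(RuntimeError):
    """Raised when probability leaks past the truncated count support."""


@dataclass
class CountDistribution:
    """Time-indexed probability mass q(n, t) on support 0..n_max."""

    times: np.ndarray
    q: np.ndarray  # (n_times, n_max + 1)

    @property
    def n_max(self) -> int:
        return self.q.shape[1] - 1

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.q.shape[1])

    def at(self, t: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))[0]
        if not idx.size:
            raise ValueError(f"t={t} is not an output time")
        return self.q[int(idx[0])]

    def to_csv(self, path) -> None:
        """Long-format export: columns t, n, q."""
        import pandas as pd

        n = self.support
        pd.DataFrame(
            {
                "t": np.repeat(self.times, n.size),
                "n": np.tile(n, self.times.size),
                "q": self.q.ravel(),
            }
        ).to_csv(path, index=False)


def binomial_initial_distribution(n_well: int, fov_prob: float) -> CountDistribution:
    """Field-of-view sampling law: n0 ~ Binomial(n_well, fov_prob) at t=0."""
    if not 0.0 <= fov_prob <= 1.0:
        raise ValueError("fov_prob must lie in [0, 1]")
    if n_well < 0:
        raise ValueError("n_well must be nonnegative")
    q0 = binom.pmf(np.arange(n_well + 1), n_well, fov_prob)
    return CountDistribution(times=np.array([0.0]), q=q0[None, :])


def distribution_mean(q: np.ndarray) -> float:
    return float(np.dot(np.arange(q.size), q))


def distribution_variance(q: np.ndarray) -> float:
    n = np.arange(q.size)
    m = float(np.dot(n, q))
    return float(np.dot((n - m) ** 2, q))


def _trim_q0(q0: np.ndarray, n_max: int, tail_tol: float = 1e-12) -> np.ndarray:
    out = np.zeros(n_max + 1)
    if q0.size > n_max + 1:
        if q0[n_max + 1 :].sum() > tail_tol:
            raise ValueError("initial distribution tail exceeds n_max support")
        out[:] = q0[: n_max + 1]
    else:
        out[: q0.size] = q0
    return out


def _eval_rate(f: Callable, t: np.ndarray) -> np.ndarray:
    vals = np.asarray(f(t), dtype=float)
    if vals.shape != t.shape:  # scalar-only callable
        vals = np.asarray([float(f(ti)) for ti in t])
    if np.any(vals < -1e-9):
        raise ValueError("event rates must be nonnegative")
    return np.maximum(vals, 0.0)


def _rk4_cme(
    r_prol: Callable, r_death: Callable, q0: np.ndarray, times: np.ndarray, dt: float
) -> np.ndarray:
    """Fixed-step RK4 on the tridiagonal birth-death generator.

    The generator spectral radius is about n_max * (r_prol + r_death), well
    inside the RK4 stability region for the default step at default rates.
    Rates are pre-evaluated on the half-step grid of each output interval.
    """
    n = np.arange(q0.size, dtype=float)
    n_lo = n[:-1]
    n_hi = n[1:]

    def deriv(q, rp, rd):
        dq = (-(rp + rd)) * (n * q)
        dq[1:] += rp * (n_lo * q[:-1])
        dq[:-1] += rd * (n_hi * q[1:])
        return dq

    out = np.empty((times.size, q0.size))
    out[0] = q0
    q = q0.copy()
    for k in range(times.size - 1):
        t0, t1 = times[k], times[k + 1]
        n_sub = max(1, int(math.ceil((t1 - t0) / dt - 1e-12)))
        h = (t1 - t0) / n_sub
        stage_t = t0 + 0.5 * h * np.arange(2 * n_sub + 1)
        rp_s = _eval_rate(r_prol, stage_t)
        rd_s = _eval_rate(r_death, stage_t)
        for j in range(n_sub):
            a, b, c = 2 * j, 2 * j + 1, 2 * j + 2
            k1 = deriv(q, rp_s[a], rd_s[a])
            k2 = deriv(q + 0.5 * h * k1, rp_s[b], rd_s[b])
            k3 = deriv(q + 0.5 * h * k2, rp_s[b], rd_s[b])
            k4 = deriv(q + h * k3, rp_s[c], rd_s[c])
            q = q + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = q
    return out


def solve_count_cme(
    r_prol: Callable,
    r_death: Callable,
    q0: np.ndarray,
    times: Sequence[float],
    n_max: int = 512,
    dt: float = 0.005,
    leak_tol: float = 1e-8,
    n_max_cap: int = 8192,
) -> CountDistribution:
    """Integrate the count master equation driven by interpolable rates.

    ``q0`` is the initial pmf on 0..len(q0)-1.  The support is truncated at
    ``n_max``; if more than ``leak_tol`` probability leaks past the cap at
    any output time the support is doubled and the solve repeated, up to
    ``n_max_cap``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    q0 = np.asarray(q0, dtype=float)
    if np.any(q0 < -1e-12):
        raise ValueError("initial pmf must be nonnegative")

    # keep the explicit integrator inside its stability region: the
    # generator's spectral radius is ~ n_max * max(r_prol + r_death)
    t_probe = np.linspace(times[0], times[-1], 101)
    rate_max = max(
        1e-12, float(np.max(_eval_rate(r_prol, t_probe) + _eval_rate(r_death, t_probe)))
    )

    cap = n_max
    while True:
        dt_eff = min(dt, 1.5 / (cap * rate_max))
        q_init = _trim_q0(q0, cap)
        q = _rk4_cme(r_prol, r_death, q_init, times, dt_eff)
        # births out of the top support state are not re-injected, so the
        # truncation leak shows up as a probability deficit.
        leak = np.max(1.0 - q.sum(axis=1))
        if leak <= leak_tol:
            return CountDistribution(times=times, q=np.maximum(q, 0.0))
        if 2 * cap > n_max_cap:
            raise TruncationError(
                f"truncation leak {np.max(np.abs(leak)):.2e} persists at "
                f"n_max={cap}; cap {n_max_cap} reached"
            )
        cap *= 2


def count_quantiles(
    dist: CountDistribution, t: float, levels: Sequence[float]
) -> np.ndarray:
    """Smallest n with CDF(n) >= level, per level."""
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    cdf = np.cumsum(dist.at(t))
    return np.searchsorted(cdf, levels, side="left").astype(int)


# ---------------------------------------------------------------------------
# Discrete two-state (binary) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteModelParams:
    """Drug-indexed parameters of the two-state switch model.

    Each field is a pair ``(value_off, value_on)`` indexed by the drug
    indicator d: switching rates r01 (sensitive->resistant) and r10, and net
    growth rates lam0 (sensitive) and lam1 (resistant), all per day.
    """

    r01: Tuple[float, float] = (0.02, 1.0)
    r10: Tuple[float, float] = (0.5, 0.01)
    lam0: Tuple[float, float] = (0.15, -0.3)
    lam1: Tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.r01 + self.r10):
            raise ValueError("switching rates must be nonnegative")

    def at(self, d: int) -> Tuple[float, float, float, float]:
        if d not in (0, 1):
            raise ValueError("drug indicator must be 0 or 1")
        return self.r01[d], self.r10[d], self.lam0[d], self.lam1[d]

    def to_dict(self) -> dict:
        return {
            name: list(getattr(self, name)) for name in ("r01", "r10", "lam0", "lam1")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteModelParams":
        """JSON block with drug-indexed pairs (off, on) per rate."""
        kwargs = {k: tuple(v) for k, v in d.items()}
        return cls(**kwargs)


def _discrete_matrix(dp: DiscreteModelParams, d: int) -> np.ndarray:
    r01, r10, l0, l1 = dp.at(d)
    return np.array([[l0 - r01, r10], [r01, l1 - r10]])


def discrete_mean_counts(
    dp: DiscreteModelParams,
    schedule: TreatmentSchedule,
    n_init: Tuple[float, float],
    times: Sequence[float],
) -> np.ndarray:
    """Mean subpopulation counts (n0(t), n1(t)); linear 2-ODE per segment."""
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, 2))
    state = np.asarray(n_init, dtype=float)
    out_idx = 0
    if times[0] == 0.0:
        out[0] = state
        out_idx = 1
    t_end = float(times[-1])
    from scipy.linalg import expm

    for (t0, t1, d) in schedule.segments(t_end):
        A = _discrete_matrix(dp, d)
        t_cur = t0
        while out_idx < times.size and times[out_idx] <= t1 + 1e-12:
            state = expm(A * (times[out_idx] - t_cur)) @ state
            t_cur = times[out_idx]
            out[out_idx] = state
            out_idx += 1
        if t_cur < t1:
            state = expm(A * (t1 - t_cur)) @ state
    return out


def discrete_mean_phenotype_coeffs(
    dp: DiscreteModelParams, d: int
) -> Tuple[float, float, float]:
    """Coefficients (A, B, C) of the mean resistant-fraction ODE
    dx/dt = A + B x + C x**2 implied by the two-state model."""
    r01, r10, l0, l1 = dp.at(d)
    return (r01, l1 - l0 - r01 - r10, l0 - l1)


def continuous_equivalent(dp: DiscreteModelParams) -> ModelSpec:
    """Continuous homogeneous model matching the discrete model's mean count.

    The resistant fraction x(t) = n1/(n0+n1) of the discrete mean ODEs obeys
    dx/dt = A(d) + B(d) x + C(d) x**2, and the mean per-capita growth rate of
    the mixture is exactly linear in x: lam(x, d) = lam0(d) +
    (lam1(d) - lam0(d)) x.  A homogeneous (beta = 0) continuous model with
    that quadratic velocity and linear growth law therefore reproduces the
    discrete mean count exactly, for any treatment schedule.
    """
    return ModelSpec(
        growth=GrowthParams(
            gamma1=dp.lam0[0], gamma2=dp.lam0[1],
            gamma3=dp.lam1[0], gamma4=dp.lam1[1],
        ),
        velocity=VelocityParams(
            form="QUADRATIC",
            quad_off=discrete_mean_phenotype_coeffs(dp, 0),
            quad_on=discrete_mean_phenotype_coeffs(dp, 1),
        ),
        diffusion=DiffusionParam(0.0),
        schedule=TreatmentSchedule(),
    )


def _joint_generator(dp: DiscreteModelParams, d: int, cap0: int, cap1: int):
    """Sparse generator of the joint (n0, n1) master equation for fixed d.

    Reactions: birth in class k at rate max(0, lam_k) n_k, death at
    -min(0, lam_k) n_k, switching 0->1 at r01 n0 and 1->0 at r10 n1.
    """
    r01, r10, l0, l1 = dp.at(d)
    b0, d0 = max(0.0, l0), max(0.0, -l0)
    b1, d1 = max(0.0, l1), max(0.0, -l1)

    m0, m1 = cap0 + 1, cap1 + 1
    idx = lambda n0, n1: n0 * m1 + n1
    n0g, n1g = np.meshgrid(np.arange(m0), np.arange(m1), indexing="ij")
    n0f, n1f = n0g.ravel(), n1g.ravel()
    rows, cols, vals = [], [], []

    def add(rate, dn0, dn1):
        src = rate > 0
        n0s, n1s, r = n0f[src], n1f[src], rate[src]
        n0d, n1d = n0s + dn0, n1s + dn1
        ok = (n0d >= 0) & (n0d <= cap0) & (n1d >= 0) & (n1d <= cap1)
        # outflow always leaves the source state (off-cap flux is the leak)
        rows.append(idx(n0s, n1s)); cols.append(idx(n0s, n1s)); vals.append(-r)
        rows.append(idx(n0d[ok], n1d[ok])); cols.append(idx(n0s[ok], n1s[ok]))
        vals.append(r[ok])

    add(b0 * n0f, +1, 0)
    add(d0 * n0f, -1, 0)
    add(b1 * n1f, 0, +1)
    add(d1 * n1f, 0, -1)
    add(r01 * n0f, -1, +1)
    add(r10 * n1f, +1, -1)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = coo_matrix((vals, (rows, cols)), shape=(m0 * m1, m0 * m1)).tocsr()
    return A


def solve_discrete_joint_cme(
    dp: DiscreteModelParams,
    schedule: TreatmentSchedule,
    init: np.ndarray,
    times: Sequence[float],
    cap0: int = 256,
    cap1: int = 256,
    leak_tol: float = 1e-8,
) -> Tuple[CountDistribution, np.ndarray]:
    """Exact joint master equation of the two-state model.

    ``init`` is the joint pmf on (n0, n1), shape (cap0+1, cap1+1) or smaller
    (zero-padded).  Returns the total-count distribution q(n, t) with
    n = n0 + n1, and the joint pmf at the final time (reshaped).
    """
    times = np.asarray(times, dtype=float)
    m0, m1 = cap0 + 1, cap1 + 1
    p0 = np.zeros((m0, m1))
    init = np.asarray(init, dtype=float)
    if init.shape[0] > m0 or init.shape[1] > m1:
        raise ValueError("initial joint pmf exceeds the caps")
    p0[: init.shape[0], : init.shape[1]] = init

    from scipy.sparse.linalg import expm_multiply

    t_end = float(times[-1])
    q_tot = np.zeros((times.size, cap0 + cap1 + 1))
    n_tot = (
        np.arange(m0)[:, None] + np.arange(m1)[None, :]
    ).ravel()

    p = p0.ravel()
    out_idx = 0
    if times[0] == 0.0:
        q_tot[0] = np.bincount(n_tot, weights=p, minlength=cap0 + cap1 + 1)
        out_idx = 1
    for (t0, t1, d) in schedule.segments(t_end):
        A = _joint_generator(dp, d, cap0, cap1)
        t_cur = t0
        while out_idx < times.size and times[out_idx] <= t1 + 1e-12:
            p = expm_multiply(A * (times[out_idx] - t_cur), p)
            t_cur = times[out_idx]
            leak = 1.0 - p.sum()
            if leak > leak_tol:
                raise TruncationError(
                    f"joint-CME leak {leak:.2e} at t={t_cur:g}; raise the caps"
                )
            q_tot[out_idx] = np.bincount(
                n_tot, weights=np.maximum(p, 0.0), minlength=cap0 + cap1 + 1
            )
            out_idx += 1
        if t_cur < t1:
            p = expm_multiply(A * (t1 - t_cur), p)
    return (
        CountDistribution(times=times, q=q_tot),
        p.reshape(m0, m1),
    )
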