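"""Exact log-likelihoods for the three observation modalities.

* Count data: the count master equation solved per condition gives
  q(n, t | theta); the log-likelihood is the sum of log q over all
  (condition, time, replicate) records, observations being independent
  across termination times and replicates.
* Event-timing data: with per-capita rates r_prol(t), r_death(t) from the
  structured density and observed population N(t), the number of events in
  a bin of width dt is Poisson with mean r(t) N(t) dt.
* Marker data: the measurement density is the convolution of the phenotype
  density p(x, t) with the noise law (Gaussian or translated Gamma); the
  log-likelihood sums log densities over cells.

A single structured-density + master-equation solve is shared by all
records of a condition; parameter vectors are plain dicts on the natural
scale, with the ``ThetaVector`` helper mapping between them and the
transformed (optimiser / sampler) space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gamma as gamma_dist, norm, poisson

from .cme import TruncationError, binomial_initial_distribution, solve_count_cme
from .datasets import CountDataset, EventDataset, MarkerDataset
from .model_core import (
    DiffusionParam,
    GrowthParams,
    ModelSpec,
    TreatmentSchedule,
    VelocityParams,
    stationary_phenotype_params,
)
from .pde import (
    PhenotypeGrid,
    default_times,
    phenotype_pdf,
    rate_interpolants,
    solve_structured_density,
)
from .synthetic_data import MarkerNoiseParams

__all__ = [
    "ThetaVector",
    "SolverOptions",
    "MarkerNoiseParams",
    "spec_from_params",
    "loglik_counts",
    "loglik_event_timings",
    "loglik_marker",
    "log_posterior",
    "marker_density",
    "LOG_FLOOR",
]

LOG_FLOOR = math.log(1e-300)

# parameters conventionally explored on a log10 scale (positive, scale-like)
LOG10_PARAMS = frozenset({"nu", "beta", "sigma"})

GAMMA_NAMES = ("gamma1", "gamma2", "gamma3", "gamma4")


@dataclass(frozen=True)
class ThetaVector:
    """Ordered free-parameter vector with fixed complement.

    ``free_names`` orders the sampled/optimised parameters; ``fixed`` holds
    the remaining parameters at set values (natural scale).  Parameters in
    ``LOG10_PARAMS`` are represented on the log10 scale in the transformed
    vector handed to optimisers and samplers.
    """

    free_names: Tuple[str, ...]
    fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.free_names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")

    def to_params(self, z: Sequence[float]) -> Dict[str, float]:
        """Transformed vector -> natural-scale parameter dict."""
        z = np.asarray(z, dtype=float)
        if z.size != len(self.free_names):
            raise ValueError("vector length does not match free parameters")
        params = dict(self.fixed)
        for name, val in zip(self.free_names, z):
            params[name] = 10.0 ** val if name in LOG10_PARAMS else float(val)
        return params

    def from_params(self, params: Dict[str, float]) -> np.ndarray:
        """Natural-scale dict -> transformed vector (free parameters only)."""
        out = []
        for name in self.free_names:
            v = params[name]
            if name in LOG10_PARAMS:
                if v <= 0:
                    raise ValueError(f"{name} must be positive for log10 transform")
                out.append(math.log10(v))
            else:
                out.append(float(v))
        return np.asarray(out)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings shared by the likelihood evaluations.

    ``rate_cap`` bounds the per-capita rates handed to the master equation;
    it only binds at parameter proposals whose growth rates are far outside
    the biologically plausible range, where the likelihood is at the log
    floor regardless.
    """

    grid: PhenotypeGrid = field(default_factory=PhenotypeGrid)
    pde_dt: float = 0.01
    rate_step: float = 0.05
    cme_n_max: int = 512
    cme_dt: float = 0.005
    rate_cap: float = 50.0

    @classmethod
    def fast(cls) -> "SolverOptions":
        """Coarser settings for optimisation / sampling inner loops."""
        return cls(
            grid=PhenotypeGrid(n_nodes=201),
            pde_dt=0.02,
            rate_step=0.1,
            cme_n_max=256,
            cme_dt=0.01,
        )


def spec_from_params(
    params: Dict[str, float],
    schedule: TreatmentSchedule,
    velocity_form: str = "OU",
) -> ModelSpec:
    """Assemble a ModelSpec from a flat parameter dict.

    Recognised keys: gamma1..gamma4, beta, and either nu (OU) or a, b, c, d
    (GENERAL drug-on family).  Missing growth/diffusion keys fall back to 0.
    """
    growth = GrowthParams(*(float(params.get(g, 0.0)) for g in GAMMA_NAMES))
    beta = float(params.get("beta", 0.0))
    if velocity_form == "OU":
        vel = VelocityParams(form="OU", nu=float(params["nu"]))
    elif velocity_form == "GENERAL":
        vel = VelocityParams(
            form="GENERAL",
            a=float(params.get("a", 0.0)),
            b=float(params.get("b", 0.0)),
            c=float(params.get("c", 0.0)),
            d=float(params.get("d", 0.0)),
        )
    else:
        raise ValueError(f"unsupported velocity form {velocity_form!r}")
    return ModelSpec(
        growth=growth,
        velocity=vel,
        diffusion=DiffusionParam(beta),
        schedule=schedule,
    )


def _initial_density(spec: ModelSpec, P: int) -> Tuple[float, float, float]:
    if spec.velocity.form == "OU":
        mean, sd = stationary_phenotype_params(P, spec.velocity, spec.diffusion)
    else:
        # GENERAL family: experiments start from the sensitive equilibrium;
        # with beta > 0 there is no closed stationary form, so seed at the
        # OU-like width around the starting state.
        mean = float(P)
        sd = 0.0 if spec.diffusion.beta == 0 else spec.diffusion.beta
    return (1.0, mean, max(sd, 0.0))


def _condition_solution(
    spec: ModelSpec, P: int, t_end: float, opts: SolverOptions
):
    times = default_times(t_end, opts.rate_step)
    return solve_structured_density(
        spec,
        _initial_density(spec, P),
        times,
        grid=opts.grid,
        dt=opts.pde_dt,
        strict_boundary=False,
    )


def loglik_counts(
    data: CountDataset,
    params: Dict[str, float],
    velocity_form: str = "OU",
    opts: Optional[SolverOptions] = None,
) -> float:
    """CME-based log-likelihood of terminal count data.

    One structured-density + master-equation solve per condition is shared
    across that condition's times and replicates; q values below the
    support of double precision contribute a fixed log floor so global
    optimisers remain usable.
    """
    opts = opts or SolverOptions()
    design = data.metadata.get("design", {})
    n_well = int(design.get("n_well", 1000))
    fov_prob = float(design.get("fov_prob", 817.0 * 614.0 / (4500.0 ** 2 * math.pi)))
    q0 = binomial_initial_distribution(n_well, fov_prob).q[0]

    mean0 = n_well * fov_prob
    total = 0.0
    for cond in data.conditions():
        sub = data.df[data.df["condition_id"] == cond.condition_id]
        spec = spec_from_params(
            params, cond.schedule(data.schedules), velocity_form
        )
        t_obs = np.sort(sub["t_days"].unique())
        t_end = float(t_obs[-1])
        sol = _condition_solution(spec, cond.P, t_end, opts)
        fp, fd = rate_interpolants(sol)
        cap = opts.rate_cap
        fp_c = lambda t, f=fp: np.minimum(np.asarray(f(t), dtype=float), cap)
        fd_c = lambda t, f=fd: np.minimum(np.asarray(f(t), dtype=float), cap)

        # cheap screen: the CME mean is mean0 * exp(int (r_prol - r_death)).
        # Parameter proposals whose predicted mean dwarfs the observable
        # range would cost enormous truncated supports for a likelihood that
        # is at the log floor anyway; penalise them monotonically instead.
        net = np.clip(sol.r_prol, None, cap) - np.clip(sol.r_death, None, cap)
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (net[1:] + net[:-1]) * np.diff(sol.times))]
        )
        n_obs_max = int(sub["count"].max())
        mean_cap = max(16.0 * n_obs_max, 16.0 * mean0, 256.0)
        log_worst = math.log(mean0) + float(cum.max())
        if log_worst > math.log(mean_cap):
            excess = log_worst - math.log(mean_cap)
            total += len(sub) * LOG_FLOOR * (1.0 + excess)
            continue

        n_max = opts.cme_n_max
        while n_max < 2 * n_obs_max + 10:
            n_max *= 2
        cme_times = np.concatenate([[0.0], t_obs.astype(float)])
        try:
            dist = solve_count_cme(
                fp_c, fd_c, q0, cme_times, n_max=n_max, dt=opts.cme_dt,
                n_max_cap=max(4096, 4 * n_max),
            )
        except TruncationError:
            # overdispersed proposal whose tail cannot be contained: treat
            # every record as at the floor (the fit is hopeless there)
            total += len(sub) * LOG_FLOOR
            continue
        for t, grp in sub.groupby("t_days"):
            q_t = dist.at(float(t))
            ns = grp["count"].to_numpy()
            if ns.max() > dist.n_max:
                raise ValueError(
                    f"observed count {ns.max()} exceeds CME support {dist.n_max}"
                )
            with np.errstate(divide="ignore"):
                logq = np.log(q_t[ns])
            total += float(np.sum(np.maximum(logq, LOG_FLOOR)))
    return total


def loglik_event_timings(
    events: EventDataset,
    params: Dict[str, float],
    velocity_form: str = "OU",
    opts: Optional[SolverOptions] = None,
    P: int = 0,
    schedule: Optional[TreatmentSchedule] = None,
) -> float:
    """Poisson log-likelihood of binned event counts.

    Per-capita rates are evaluated at bin midpoints; the observed
    population at the bin start scales the Poisson means.  A bin with no
    cells but recorded events is impossible under the model (-inf).
    """
    opts = opts or SolverOptions()
    schedule = schedule or TreatmentSchedule.continuous(True)
    spec = spec_from_params(params, schedule, velocity_form)
    df = events.df
    t_end = float(df["bin_end"].max())
    sol = _condition_solution(spec, P, t_end, opts)
    fp, fd = rate_interpolants(sol)

    mids = 0.5 * (df["bin_start"].to_numpy() + df["bin_end"].to_numpy())
    widths = df["bin_end"].to_numpy() - df["bin_start"].to_numpy()
    n_start = df["n_at_start"].to_numpy().astype(float)
    births = df["n_prolif_events"].to_numpy()
    deaths = df["n_death_events"].to_numpy()
    rp = np.maximum(np.asarray([fp(t) for t in mids], dtype=float), 0.0)
    rd = np.maximum(np.asarray([fd(t) for t in mids], dtype=float), 0.0)

    empty = n_start == 0
    if np.any(empty & ((births > 0) | (deaths > 0))):
        return -math.inf
    mu_p = rp * n_start * widths
    mu_d = rd * n_start * widths
    # Poisson(0) is a point mass at zero
    ll = 0.0
    for mu, k in ((mu_p, births), (mu_d, deaths)):
        zero = mu <= 0
        if np.any(zero & (k > 0)):
            return -math.inf
        ll += float(np.sum(poisson.logpmf(k[~zero], mu[~zero])))
    return ll


def _noise_logpdf(e: np.ndarray, noise: MarkerNoiseParams) -> np.ndarray:
    if noise.omega == 0.0:
        return norm.logpdf(e, scale=noise.sigma)
    k = 4.0 / noise.omega ** 2
    s = noise.sigma * abs(noise.omega) / 2.0
    z = e if noise.omega > 0 else -e
    return gamma_dist.logpdf(z + k * s, k, scale=s)


def marker_density(
    sol, t: float, noise: MarkerNoiseParams, support: Optional[Tuple[float, float]] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Density of the marker M = x + eps at output time t, on an extended
    grid (trapezoidal convolution of the phenotype pdf with the noise law).

    ``support`` forces the returned grid to cover at least that marker
    range, so observed values far in the tails evaluate to a (tiny) density
    rather than falling off the grid.
    """
    pad = 6.0 * noise.sigma * (1.0 + abs(noise.omega))
    if sol.homogeneous:
        idx = np.nonzero(np.isclose(sol.times, t, rtol=0, atol=1e-9))[0]
        if not idx.size:
            raise ValueError(f"t={t} is not an output time")
        x0 = float(sol.x_bar[int(idx[0])])
        lo, hi = x0 - pad, x0 + pad
        if support is not None:
            lo = min(lo, support[0] - 1e-9)
            hi = max(hi, support[1] + 1e-9)
        m = np.linspace(lo, hi, 1201)
        return m, np.exp(_noise_logpdf(m - x0, noise))
    x = sol.grid.nodes
    h = sol.grid.h
    p = phenotype_pdf(sol, t)
    if support is not None:
        pad = max(pad, x[0] - support[0] + h, support[1] - x[-1] + h)
    n_pad = int(math.ceil(pad / h))
    offsets = np.arange(-n_pad, n_pad + 1) * h
    kernel = np.exp(_noise_logpdf(offsets, noise))
    dens = np.convolve(p, kernel, mode="full") * h
    m = x[0] + (np.arange(dens.size) - n_pad) * h
    return m, dens


def loglik_marker(
    markers: MarkerDataset,
    params: Dict[str, float],
    noise: MarkerNoiseParams,
    velocity_form: str = "OU",
    opts: Optional[SolverOptions] = None,
    P: int = 0,
    schedule: Optional[TreatmentSchedule] = None,
) -> float:
    """Log-likelihood of per-cell marker values under the convolved density."""
    opts = opts or SolverOptions()
    schedule = schedule or TreatmentSchedule.continuous(True)
    spec = spec_from_params(params, schedule, velocity_form)
    df = markers.df
    t_end = float(df["t_days"].max())
    sol = _condition_solution(spec, P, t_end, opts)

    support = (float(df["marker_value"].min()), float(df["marker_value"].max()))
    total = 0.0
    for t, grp in df.groupby("t_days"):
        m_grid, dens = marker_density(sol, float(t), noise, support=support)
        vals = grp["marker_value"].to_numpy()
        dens_at = np.interp(vals, m_grid, dens)
        with np.errstate(divide="ignore"):
            total += float(
                np.sum(np.maximum(np.log(np.maximum(dens_at, 0.0)), LOG_FLOOR))
            )
    return total


def log_posterior(
    z: Sequence[float],
    theta: ThetaVector,
    prior_box,
    loglik: Callable[[Dict[str, float]], float],
) -> float:
    """Unnormalised log posterior on the transformed scale.

    With the independent uniform prior box the posterior is the likelihood
    restricted to the box, so the MAP coincides with the MLE.
    """
    z = np.asarray(z, dtype=float)
    if not prior_box.contains(theta.free_names, z):
        return -math.inf
    return float(loglik(theta.to_params(z)))
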