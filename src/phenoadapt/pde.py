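"""Structured-density (Fokker-Planck + reaction) solver.

The cell density u(x, t) over the phenotype index obeys

    du/dt + d(v u)/dx = (beta**2 / 2) d2u/dx2 + lambda(x, Tx) u,

with no-flux boundaries on a truncated domain.  Derived quantities are the
expected cell count <N>(t) = integral of u, the phenotype PDF
p(x, t) = u / <N>, and the per-capita event rates

    r_prol(t) = int p max(0, lambda) dx,
    r_death(t) = -int p min(0, lambda) dx,

which drive the count-level master equation.

Numerics: conservative finite-volume discretisation with Chang-Cooper
exponential-fitted advection (exact for the stationary drift-diffusion
balance, reduces to upwinding as beta -> 0, and adds no spurious numerical
diffusion), Crank-Nicolson time stepping segmented at drug-switch times.
For beta = 0 exactly the density is a travelling atom and the solver
switches to the characteristic form: it evolves the phenotype path x(t) and
log N(t) as ODEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.linalg import solve_banded

from .model_core import ModelSpec, GrowthParams, growth_rate, velocity

__all__ = [
    "PhenotypeGrid",
    "PDESolution",
    "GridTruncationError",
    "solve_structured_density",
    "expected_count",
    "phenotype_pdf",
    "event_rates",
    "rate_interpolants",
    "default_times",
]


class GridTruncationError(RuntimeError):
    """Raised when significant density mass reaches the domain boundary."""


@dataclass(frozen=True)
class PhenotypeGrid:
    """Uniform phenotype mesh truncating the real line.

    The domain must contain both equilibria (0 and 1) strictly; the default
    [-0.5, 1.5] leaves ~9 stationary standard deviations to each boundary at
    the default parameters, so boundary mass is negligible.
    """

    x_min: float = -0.5
    x_max: float = 1.5
    n_nodes: int = 401

    def __post_init__(self) -> None:
        if not (self.x_min < 0.0 < 1.0 < self.x_max):
            raise ValueError("grid must satisfy x_min < 0 < 1 < x_max")
        if self.n_nodes < 101:
            raise ValueError("n_nodes must be at least 101")

    @property
    def h(self) -> float:
        return (self.x_max - self.x_min) / (self.n_nodes - 1)

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_nodes)


@dataclass
class PDESolution:
    """Solution container: density (or phenotype path for beta=0) plus
    derived expected count and per-capita event rates on the output times."""

    spec: ModelSpec
    times: np.ndarray
    grid: Optional[PhenotypeGrid]
    u: Optional[np.ndarray]  # (n_times, n_nodes); None in homogeneous mode
    n_mean: np.ndarray
    r_prol: np.ndarray
    r_death: np.ndarray
    x_bar: Optional[np.ndarray] = None  # homogeneous (beta=0) phenotype path

    @property
    def homogeneous(self) -> bool:
        return self.u is None

    def density_to_csv(self, path) -> None:
        """Long-format export of u(x, t): columns t, x, u."""
        import pandas as pd

        if self.homogeneous:
            raise ValueError("beta=0 solution has no grid density to export")
        x = self.grid.nodes
        pd.DataFrame(
            {
                "t": np.repeat(self.times, x.size),
                "x": np.tile(x, self.times.size),
                "u": self.u.ravel(),
            }
        ).to_csv(path, index=False)

    def summary_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "t": self.times,
                "expected_count": self.n_mean,
                "r_prol": self.r_prol,
                "r_death": self.r_death,
            }
        ).to_csv(path, index=False)


def default_times(t_end: float, step: float = 0.05) -> np.ndarray:
    """Output-time grid dense enough to interpolate the event rates."""
    n = max(2, int(round(t_end / step)) + 1)
    return np.linspace(0.0, t_end, n)


def _chang_cooper_delta(w: np.ndarray) -> np.ndarray:
    """Exponential-fitting weight on the upwind node:
    delta(w) = 1/(1 - e^-w) - 1/w; delta(0) = 1/2, -> 1 as w -> +inf."""
    out = np.empty_like(w)
    small = np.abs(w) < 1e-8
    ws = w[~small]
    out[~small] = 1.0 + 1.0 / np.expm1(ws) - 1.0 / ws
    out[small] = 0.5 + w[small] / 12.0
    return out


def _operator_diagonals(
    spec: ModelSpec, grid: PhenotypeGrid, tx: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal generator A (lower, main, upper diagonals) for fixed Tx."""
    x = grid.nodes
    h = grid.h
    n = grid.n_nodes
    D = 0.5 * spec.diffusion.beta ** 2
    x_face = 0.5 * (x[:-1] + x[1:])
    v_face = np.asarray(velocity(x_face, tx, spec.velocity), dtype=float)
    if D > 0:
        w = v_face * h / D
        delta = _chang_cooper_delta(w)
        a_face = v_face * delta + D / h          # coefficient of u_j in F_{j+1/2}
        b_face = v_face * (1.0 - delta) - D / h  # coefficient of u_{j+1}
    else:
        # pure advection: full upwinding
        a_face = np.where(v_face > 0, v_face, 0.0)
        b_face = np.where(v_face < 0, v_face, 0.0)

    lam = np.asarray(growth_rate(x, tx, spec.growth), dtype=float)
    main = lam.copy()
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    # du_j/dt -= F_{j+1/2}/h for j=0..n-2 ; du_{j+1}/dt += F_{j+1/2}/h
    main[:-1] -= a_face / h
    upper += -b_face / h
    lower += a_face / h
    main[1:] += b_face / h
    return lower, main, upper


def _cn_step_matrices(lower, main, upper, dt):
    """Banded LHS (I - dt/2 A) for solve_banded, and RHS diagonals."""
    n = main.size
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * dt * upper
    ab[1, :] = 1.0 - 0.5 * dt * main
    ab[2, :-1] = -0.5 * dt * lower
    return ab


def _gaussian_on_grid(grid: PhenotypeGrid, mass: float, mean: float, sd: float) -> np.ndarray:
    x = grid.nodes
    if sd <= 0:
        raise ValueError("initial sd must be positive for the density solver")
    u = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    total = np.trapezoid(u, x)
    if total <= 0:
        # all mass outside the grid: park it at the nearest boundary cell
        u = np.zeros_like(x)
        u[0 if mean < 0.5 * (grid.x_min + grid.x_max) else -1] = 1.0
        total = np.trapezoid(u, x) or 1.0
    u *= mass / total
    return u


def _rates_from_pdf(p: np.ndarray, lam: np.ndarray, x: np.ndarray) -> Tuple[float, float]:
    rp = np.trapezoid(p * np.maximum(0.0, lam), x)
    rd = -np.trapezoid(p * np.minimum(0.0, lam), x)
    # guard against degenerate densities (e.g. underflowed total mass)
    rp = float(np.nan_to_num(rp, nan=0.0, posinf=1e6))
    rd = float(np.nan_to_num(rd, nan=0.0, posinf=1e6))
    return min(rp, 1e6), min(rd, 1e6)


def solve_structured_density(
    spec: ModelSpec,
    init: Union[Tuple[float, float, float], np.ndarray],
    times: Sequence[float],
    grid: Optional[PhenotypeGrid] = None,
    dt: float = 0.01,
    boundary_tol: float = 1e-6,
    strict_boundary: bool = True,
) -> PDESolution:
    """Solve the structured-density PDE on the given output times.

    ``init`` is either ``(mass, mean, sd)`` describing a Gaussian initial
    density (the stationary seeding law), or an explicit density array on
    the grid.  ``dt`` is the Crank-Nicolson step; output times are hit
    exactly by sub-stepping.  Drug switch times segment the integration.

    For ``beta == 0`` the solution is the homogeneous characteristic form:
    ``u`` is ``None`` and ``x_bar`` carries the deterministic phenotype path.
    The same form is used when beta is too small for the density width to be
    resolved on the grid (the induced rate error is O(beta**2) there, far
    below the discretisation noise a smeared atom would produce).

    ``strict_boundary=False`` clips out-of-domain initial mass onto the grid
    and skips boundary-mass errors; use it inside likelihood evaluations,
    where implausible parameter proposals must yield a finite (poor)
    likelihood rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] != 0.0:
        raise ValueError("times must be a 1-D array starting at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    grid = grid or PhenotypeGrid()
    beta = spec.diffusion.beta
    if not isinstance(init, np.ndarray):
        # width the density will actually attain over the experiment
        if spec.velocity.form == "OU":
            width = beta / math.sqrt(2.0 * spec.velocity.nu)
        else:
            width = beta * math.sqrt(2.0 * float(times[-1]))
        if width < 2.0 * grid.h:
            return _solve_homogeneous(spec, init, times)
    elif beta == 0.0:
        raise ValueError("homogeneous (beta=0) mode requires (mass, mean, sd) init")

    x = grid.nodes
    if isinstance(init, np.ndarray):
        u0 = np.asarray(init, dtype=float)
        if u0.shape != x.shape:
            raise ValueError("explicit initial density must match the grid")
    else:
        mass, mean, sd = init
        u0 = _gaussian_on_grid(grid, mass, mean, sd)
    total0 = np.trapezoid(u0, x)
    if strict_boundary and (u0[0] + u0[-1]) * grid.h > 1e-10 * total0:
        raise GridTruncationError(
            "initial density has non-negligible mass at the domain boundary; "
            "widen the grid"
        )

    t_end = float(times[-1])
    segments = spec.schedule.segments(t_end)

    n_t = times.size
    u_out = np.empty((n_t, grid.n_nodes))
    u_out[0] = u0
    u = u0.copy()
    out_idx = 1

    for (t0, t1, tx) in segments:
        lower, main, upper = _operator_diagonals(spec, grid, tx)
        # output times strictly inside (t0, t1], plus the segment end
        targets = [t for t in times[out_idx:] if t0 < t <= t1]
        if not targets or targets[-1] < t1:
            targets = targets + [t1]
        t_cur = t0
        ab_cache = {}
        for t_next in targets:
            span = t_next - t_cur
            if span <= 0:
                continue
            n_sub = max(1, int(math.ceil(span / dt - 1e-12)))
            dt_sub = span / n_sub
            key = round(dt_sub, 15)
            if key not in ab_cache:
                ab_cache[key] = _cn_step_matrices(lower, main, upper, dt_sub)
            ab = ab_cache[key]
            hd = 0.5 * dt_sub
            for _ in range(n_sub):
                rhs = u + hd * (main * u)
                rhs[:-1] += hd * (upper * u[1:])
                rhs[1:] += hd * (lower * u[:-1])
                u = solve_banded((1, 1), ab, rhs)
            t_cur = t_next
            if out_idx < n_t and abs(times[out_idx] - t_next) < 1e-12:
                u_out[out_idx] = u
                out_idx += 1

    # derived quantities + boundary-mass monitoring
    n_mean = np.trapezoid(u_out, x, axis=1)
    r_prol = np.empty(n_t)
    r_death = np.empty(n_t)
    for i, t in enumerate(times):
        tx = _tx_at(spec, t)
        lam = np.asarray(growth_rate(x, tx, spec.growth), dtype=float)
        if n_mean[i] <= 0:
            raise GridTruncationError("expected count vanished during the solve")
        boundary_mass = (max(u_out[i, 0], 0.0) + max(u_out[i, -1], 0.0)) * grid.h
        if strict_boundary and boundary_mass > boundary_tol * n_mean[i]:
            raise GridTruncationError(
                f"boundary mass fraction {boundary_mass / n_mean[i]:.2e} at "
                f"t={t:g} exceeds {boundary_tol:g}; widen the grid"
            )
        p = np.maximum(u_out[i], 0.0) / n_mean[i]
        r_prol[i], r_death[i] = _rates_from_pdf(p, lam, x)

    return PDESolution(
        spec=spec, times=times, grid=grid, u=u_out,
        n_mean=n_mean, r_prol=r_prol, r_death=r_death,
    )


def _tx_at(spec: ModelSpec, t: float) -> int:
    from .model_core import drug_indicator

    return drug_indicator(t, spec.schedule)


def _solve_homogeneous(
    spec: ModelSpec, init, times: np.ndarray
) -> PDESolution:
    """beta = 0: evolve the phenotype path and log N as ODEs."""
    if isinstance(init, np.ndarray):
        raise ValueError("homogeneous (beta=0) mode requires (mass, mean, sd) init")
    mass, mean, _sd = init
    if mass <= 0:
        raise ValueError("initial mass must be positive")
    t_end = float(times[-1])

    x_bar = np.empty_like(times)
    log_n = np.empty_like(times)
    x_bar[0] = mean
    log_n[0] = math.log(mass)
    state = np.array([mean, math.log(mass)])
    out_idx = 1
    x_cap = 20.0  # freeze runaway paths; growth there is absurd anyway
    vp = spec.velocity
    sgn_width = 1e-3  # smooth the GENERAL family's sign kink so the ODE
    #                   integrator does not chatter at the x = 1 equilibrium;
    #                   the path error this induces is O(width)

    for (t0, t1, tx) in spec.schedule.segments(t_end):
        def rhs(t, y, tx=tx):
            xv = float(y[0])
            if vp.form == "GENERAL":
                if tx != 1:
                    raise ValueError("GENERAL velocity requires drug-on dynamics")
                v = vp.a * math.tanh((1.0 - xv) / sgn_width) + (1.0 - xv) * (
                    vp.b + vp.c * xv + vp.d * xv * xv
                )
            else:
                v = velocity(xv, tx, vp)
            if (xv > x_cap - 1.0 and v > 0) or (xv < -(x_cap - 1.0) and v < 0):
                # taper outward motion to zero over one unit so the path
                # settles smoothly at the cap instead of chattering on it
                v *= min(max(x_cap - abs(xv), 0.0), 1.0)
            lam = float(np.clip(growth_rate(xv, tx, spec.growth), -100.0, 100.0))
            return [v, lam]

        targets = [t for t in times[out_idx:] if t0 < t <= t1]
        eval_ts = sorted(set(targets + [t1]))
        res = solve_ivp(
            rhs, (t0, t1), state, t_eval=eval_ts, rtol=1e-8, atol=1e-10,
            method="LSODA",
        )
        if not res.success:
            raise RuntimeError(f"characteristic ODE solve failed: {res.message}")
        for j, t in enumerate(res.t):
            if out_idx < times.size and abs(times[out_idx] - t) < 1e-12:
                x_bar[out_idx] = res.y[0, j]
                log_n[out_idx] = res.y[1, j]
                out_idx += 1
        state = res.y[:, -1]

    n_mean = np.exp(np.minimum(log_n, 700.0))
    r_prol = np.empty_like(times)
    r_death = np.empty_like(times)
    for i, t in enumerate(times):
        lam = growth_rate(x_bar[i], _tx_at(spec, t), spec.growth)
        r_prol[i] = max(0.0, lam)
        r_death[i] = max(0.0, -lam)
    return PDESolution(
        spec=spec, times=times, grid=None, u=None,
        n_mean=n_mean, r_prol=r_prol, r_death=r_death, x_bar=x_bar,
    )


def _time_index(sol: PDESolution, t: float) -> Optional[int]:
    idx = np.nonzero(np.isclose(sol.times, t, rtol=0, atol=1e-9))[0]
    return int(idx[0]) if idx.size else None


def expected_count(sol: PDESolution, t: float) -> float:
    """Expected cell count <N>(t); linear interpolation between output times."""
    i = _time_index(sol, t)
    if i is not None:
        return float(sol.n_mean[i])
    if not (sol.times[0] <= t <= sol.times[-1]):
        raise ValueError(f"t={t} outside the solved time range")
    return float(np.interp(t, sol.times, sol.n_mean))


def phenotype_pdf(sol: PDESolution, t: float) -> np.ndarray:
    """Normalised phenotype density p(x, t) on the grid nodes."""
    if sol.homogeneous:
        raise ValueError(
            "beta=0 solution is an atom at x_bar(t); no grid density exists"
        )
    i = _time_index(sol, t)
    if i is None:
        raise ValueError(f"t={t} is not an output time")
    n = sol.n_mean[i]
    if n <= 0:
        raise ValueError("expected count is non-positive; degenerate state")
    return np.maximum(sol.u[i], 0.0) / n


def event_rates(sol: PDESolution, gp: GrowthParams, t: float) -> Tuple[float, float]:
    """Per-capita proliferation and death rates (per day) at output time t."""
    i = _time_index(sol, t)
    if i is None:
        raise ValueError(f"t={t} is not an output time")
    if sol.homogeneous:
        lam = growth_rate(sol.x_bar[i], _tx_at(sol.spec, t), gp)
        return max(0.0, lam), max(0.0, -lam)
    p = phenotype_pdf(sol, t)
    x = sol.grid.nodes
    lam = np.asarray(growth_rate(x, _tx_at(sol.spec, t), gp), dtype=float)
    return _rates_from_pdf(p, lam, x)


def rate_interpolants(sol: PDESolution) -> Tuple[Callable, Callable]:
    """Monotone-cubic interpolants of r_prol(t), r_death(t) between output
    times, split at drug-switch breakpoints (rates may jump there)."""
    switch = [t for t in sol.spec.schedule.switch_times if t < sol.times[-1]]
    if not switch:
        # errstate: PCHIP's harmonic-mean slope formula overflows harmlessly
        # when adjacent slopes span many orders of magnitude (extreme
        # parameter proposals); the interpolant itself is well defined
        with np.errstate(over="ignore"):
            fp = PchipInterpolator(sol.times, sol.r_prol)
            fd = PchipInterpolator(sol.times, sol.r_death)
        return fp, fd

    # piecewise PCHIP per constant-drug segment, right-continuous at switches
    bounds = [sol.times[0]] + list(switch) + [sol.times[-1]]
    pieces = []
    for t0, t1 in zip(bounds, bounds[1:]):
        mask = (sol.times >= t0 - 1e-12) & (sol.times <= t1 + 1e-12)
        ts = sol.times[mask]
        pieces.append(
            (t0, t1, PchipInterpolator(ts, sol.r_prol[mask]),
             PchipInterpolator(ts, sol.r_death[mask]))
        )

    def make(which):
        def f(t):
            t = np.asarray(t, dtype=float)
            out = np.empty_like(t)
            flat_t = np.atleast_1d(t)
            flat_o = np.atleast_1d(out)
            for i, ti in enumerate(flat_t):
                for (t0, t1, fp, fd) in pieces:
                    if (ti >= t0 and ti < t1) or (t1 == bounds[-1] and ti <= t1):
                        flat_o[i] = fp(ti) if which == 0 else fd(ti)
                        break
            return out if out.ndim else float(out)

        return f

    return make(0), make(1)
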