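"""Structured-density solver: analytic oracles, conservation, limits."""

import math

import numpy as np
import pytest

from phenoadapt import pde
from phenoadapt.model_core import (
    DiffusionParam,
    GrowthParams,
    ModelSpec,
    TreatmentSchedule,
    VelocityParams,
)

NU, BETA = 0.4, 0.05


def _ou_spec(beta=BETA, growth=(0, 0, 0, 0), drug_on=True):
    return ModelSpec(
        growth=GrowthParams(*growth),
        velocity=VelocityParams(form="OU", nu=NU),
        diffusion=DiffusionParam(beta),
        schedule=TreatmentSchedule.continuous(drug_on),
    )


def _moments(sol, t):
    x = sol.grid.nodes
    p = pde.phenotype_pdf(sol, t)
    m = np.trapezoid(p * x, x)
    v = np.trapezoid(p * (x - m) ** 2, x)
    return m, v


def test_ou_transient_moments_match_closed_form():
    """With growth off the density is an OU law; mean and variance must
    track the analytic transients to 1e-4 on a refined mesh."""
    mean0, sd0 = 0.0, 0.05
    sol = pde.solve_structured_density(
        _ou_spec(), (1.0, mean0, sd0), pde.default_times(7.0),
        grid=pde.PhenotypeGrid(n_nodes=1201), dt=0.005,
    )
    for t in (1.0, 3.0, 7.0):
        m, v = _moments(sol, t)
        m_true = 1 + (mean0 - 1) * math.exp(-NU * t)
        v_true = sd0**2 * math.exp(-2 * NU * t) + BETA**2 / (2 * NU) * (
            1 - math.exp(-2 * NU * t)
        )
        assert m == pytest.approx(m_true, abs=1e-4)
        assert v == pytest.approx(v_true, abs=1e-4)


def test_beta_zero_characteristic_mode():
    """beta = 0 solves the phenotype path ODE: x(7) = 1 - exp(-2.8)."""
    sol = pde.solve_structured_density(
        _ou_spec(beta=0.0), (1.0, 0.0, 0.0), pde.default_times(7.0)
    )
    assert sol.homogeneous
    idx = np.argmin(np.abs(sol.times - 7.0))
    assert sol.x_bar[idx] == pytest.approx(1 - math.exp(-2.8), abs=1e-8)
    with pytest.raises(ValueError):
        pde.phenotype_pdf(sol, 7.0)


def test_constant_growth_expected_count():
    """v = 0 (zero quadratic velocity), lambda = c: <N>(t) = m exp(ct)."""
    spec = ModelSpec(
        growth=GrowthParams(0.15, 0.15, 0.15, 0.15),
        velocity=VelocityParams(form="QUADRATIC"),
        diffusion=DiffusionParam(0.05),
        schedule=TreatmentSchedule.continuous(True),
    )
    m0 = 7.886
    sol = pde.solve_structured_density(spec, (m0, 0.2, 0.05), pde.default_times(7.0))
    assert pde.expected_count(sol, 0.0) == pytest.approx(m0, rel=1e-9)
    assert pde.expected_count(sol, 7.0) == pytest.approx(
        m0 * math.exp(1.05), rel=1e-5
    )


def test_fully_sensitive_decay_rate():
    """No adaptation (tiny nu not needed: use quadratic v=0), drug on,
    x = 0 everywhere: decay at gamma2 = 0.3/day."""
    spec = ModelSpec(
        growth=GrowthParams(),
        velocity=VelocityParams(form="QUADRATIC"),
        diffusion=DiffusionParam(0.02),
        schedule=TreatmentSchedule.continuous(True),
    )
    sol = pde.solve_structured_density(spec, (1.0, 0.0, 0.02), pde.default_times(3.0))
    assert pde.expected_count(sol, 3.0) == pytest.approx(
        math.exp(-0.3 * 3), rel=2e-3
    )


def test_pdf_normalisation_and_initial_condition():
    sol = pde.solve_structured_density(
        _ou_spec(), (5.0, 0.0, 0.05), pde.default_times(7.0)
    )
    x = sol.grid.nodes
    for t in sol.times[:: len(sol.times) // 5]:
        p = pde.phenotype_pdf(sol, float(t))
        assert np.trapezoid(p, x) == pytest.approx(1.0, abs=1e-6)
    p0 = pde.phenotype_pdf(sol, 0.0)
    gauss = np.exp(-0.5 * (x / 0.05) ** 2) / (0.05 * math.sqrt(2 * math.pi))
    assert np.max(np.abs(p0 - gauss / np.trapezoid(gauss, x))) < 1e-6


def test_long_time_pdf_is_stationary_normal():
    """Sustained drug: p(x, t) -> N(1, beta^2 / 2 nu)."""
    sol = pde.solve_structured_density(
        _ou_spec(), (1.0, 0.0, 0.05), pde.default_times(25.0)
    )
    m, v = _moments(sol, 25.0)
    assert m == pytest.approx(1.0, abs=2e-3)
    assert v == pytest.approx(BETA**2 / (2 * NU), rel=0.02)


def test_event_rates_decomposition():
    """r_prol, r_death >= 0 and their difference is the mean growth rate."""
    spec = ModelSpec()
    sol = pde.solve_structured_density(
        spec, (1.0, 0.0, BETA / math.sqrt(2 * NU)), pde.default_times(7.0)
    )
    from phenoadapt.model_core import growth_rate

    x = sol.grid.nodes
    for t in (1.0, 3.0, 5.0):
        rp, rd = pde.event_rates(sol, spec.growth, t)
        assert rp >= 0 and rd >= 0
        p = pde.phenotype_pdf(sol, t)
        net = np.trapezoid(p * growth_rate(x, 1, spec.growth), x)
        assert rp - rd == pytest.approx(net, abs=1e-10)


def test_event_rates_near_stationary_sensitive_no_drug(true_params):
    """Sensitive stationary population without drug: r_prol ~ 0.15, r_death ~ 0."""
    spec = _ou_spec(growth=(0.15, -0.3, 0.1, 0.1), drug_on=False)
    sol = pde.solve_structured_density(
        spec, (1.0, 0.0, BETA / math.sqrt(2 * NU)), pde.default_times(1.0)
    )
    rp, rd = pde.event_rates(sol, spec.growth, 0.0)
    assert rp == pytest.approx(0.15, abs=2e-3)
    assert rd == pytest.approx(0.0, abs=1e-6)


def test_mass_rate_consistency():
    """d<N>/dt = <N> (r_prol - r_death) along the solution."""
    spec = ModelSpec()
    sol = pde.solve_structured_density(
        spec, (7.9, 0.0, BETA / math.sqrt(2 * NU)), pde.default_times(7.0, 0.05)
    )
    n = sol.n_mean
    dndt = np.gradient(n, sol.times)
    rhs = n * (sol.r_prol - sol.r_death)
    interior = slice(2, -2)
    assert np.max(np.abs(dndt[interior] - rhs[interior])) < 5e-3 * np.max(n)


def test_grid_refinement_converged():
    """Halving the mesh spacing changes <N>(7) by < 0.1% at defaults."""
    spec = ModelSpec()
    init = (1.0, 0.0, BETA / math.sqrt(2 * NU))
    n7 = [
        pde.expected_count(
            pde.solve_structured_density(
                spec, init, pde.default_times(7.0),
                grid=pde.PhenotypeGrid(n_nodes=nn),
            ),
            7.0,
        )
        for nn in (401, 801)
    ]
    assert abs(n7[1] - n7[0]) / n7[0] < 1e-3


def test_beta_separates_rate_curves_only_near_transition():
    """Halving beta barely moves r_prol away from the proliferation-death
    transition; doubling beta separates the curves visibly."""
    def rates(beta):
        spec = _ou_spec(beta=beta, growth=(0.15, -0.3, 0.1, 0.1))
        sd = max(beta, 1e-3) / math.sqrt(2 * NU)
        sol = pde.solve_structured_density(
            spec, (1.0, 0.0, sd), pde.default_times(7.0, 0.05),
            strict_boundary=False,
        )
        return sol.times, sol.r_prol

    t, r_base = rates(BETA)
    _, r_half = rates(BETA / 2)
    _, r_double = rates(2 * BETA)
    peak = r_base.max()
    # transition where lambda(x_bar) crosses zero: x_bar = 0.75 at ~3.47 d
    t_star = -math.log(0.25) / NU
    away = (t < t_star - 1.0) | (t > t_star + 1.0)
    assert np.max(np.abs(r_base - r_half)[away]) < 0.05 * peak
    assert np.max(np.abs(r_base - r_double)) > np.max(np.abs(r_base - r_half))


def test_boundary_mass_error_raised():
    with pytest.raises(pde.GridTruncationError):
        pde.solve_structured_density(
            _ou_spec(), (1.0, -0.45, 0.05), pde.default_times(1.0)
        )


def test_time_interpolation_and_domain_errors():
    sol = pde.solve_structured_density(
        _ou_spec(), (1.0, 0.0, 0.05), np.array([0.0, 1.0, 2.0])
    )
    mid = pde.expected_count(sol, 1.5)
    assert min(sol.n_mean[1], sol.n_mean[2]) <= mid <= max(sol.n_mean[1], sol.n_mean[2])
    with pytest.raises(ValueError):
        pde.expected_count(sol, 5.0)
    with pytest.raises(ValueError):
        pde.phenotype_pdf(sol, 1.5)


def test_solution_csv_exports(tmp_path):
    import pandas as pd

    sol = pde.solve_structured_density(
        _ou_spec(), (1.0, 0.0, 0.05), np.array([0.0, 1.0])
    )
    sol.density_to_csv(tmp_path / "u.csv")
    sol.summary_to_csv(tmp_path / "s.csv")
    u = pd.read_csv(tmp_path / "u.csv")
    assert len(u) == 2 * sol.grid.n_nodes
    s = pd.read_csv(tmp_path / "s.csv")
    assert list(s.columns) == ["t", "expected_count", "r_prol", "r_death"]
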