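"""Count master equation and the discrete two-state model."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import binom, nbinom

from phenoadapt import cme
from phenoadapt.model_core import TreatmentSchedule
from phenoadapt.pde import default_times, rate_interpolants, solve_structured_density

RHO = 817 * 614 / (4500**2 * math.pi)


def test_binomial_initial_distribution():
    dist = cme.binomial_initial_distribution(1000, RHO)
    q0 = dist.q[0]
    assert cme.distribution_mean(q0) == pytest.approx(1000 * RHO, rel=1e-12)
    assert round(1000 * RHO, 1) == 7.9
    assert np.allclose(q0, binom.pmf(np.arange(1001), 1000, RHO))

    point0 = cme.binomial_initial_distribution(10, 0.0).q[0]
    assert point0[0] == 1.0
    point10 = cme.binomial_initial_distribution(10, 1.0).q[0]
    assert point10[10] == 1.0
    with pytest.raises(ValueError):
        cme.binomial_initial_distribution(10, 1.2)


def test_pure_birth_matches_negative_binomial():
    """Constant birth rate: the count is n0 + NB(n0, e^{-bt}) (Yule)."""
    b, n0, t = 0.2, 5, 3.0
    q0 = np.zeros(n0 + 1)
    q0[n0] = 1.0
    dist = cme.solve_count_cme(lambda s: b, lambda s: 0.0, q0, [0.0, t], n_max=256)
    qT = dist.at(t)
    n = np.arange(qT.size)
    exact = np.zeros_like(qT)
    exact[n0:] = nbinom.pmf(n[n0:] - n0, n0, math.exp(-b * t))
    assert np.max(np.abs(qT - exact)) < 1e-8


def test_constant_rates_match_matrix_exponential_oracle():
    """Independent oracle: dense expm of the truncated generator."""
    b, d, n0, t, nmax = 0.2, 0.1, 5, 2.0, 80
    A = np.zeros((nmax + 1, nmax + 1))
    for n in range(nmax + 1):
        A[n, n] -= n * (b + d)
        if n + 1 <= nmax:
            A[n + 1, n] += n * b
        if n - 1 >= 0:
            A[n - 1, n] += n * d
    q0 = np.zeros(nmax + 1)
    q0[n0] = 1.0
    oracle = expm(A * t) @ q0
    dist = cme.solve_count_cme(
        lambda s: b, lambda s: d, q0, [0.0, t], n_max=nmax, n_max_cap=nmax
    )
    assert np.max(np.abs(dist.at(t) - oracle)) < 1e-8


def test_zero_rates_freeze_distribution():
    q0 = binom.pmf(np.arange(21), 20, 0.3)
    dist = cme.solve_count_cme(lambda s: 0.0, lambda s: 0.0, q0, [0.0, 1.0, 5.0], n_max=20, n_max_cap=20)
    assert np.allclose(dist.at(5.0), q0, atol=1e-14)


def test_mean_follows_exponential_of_integrated_net_rate():
    """First-moment identity for time-varying rates."""
    rp = lambda t: 0.25 + 0.1 * np.sin(t)
    rd = lambda t: 0.1 + 0.05 * np.cos(t)
    q0 = binom.pmf(np.arange(41), 40, 0.2)
    times = [0.0, 1.0, 3.0, 6.0]
    dist = cme.solve_count_cme(rp, rd, q0, times, n_max=512)
    for t in times[1:]:
        integral = (
            0.25 * t - 0.1 * (math.cos(t) - 1) - 0.1 * t - 0.05 * math.sin(t)
        )
        expected = 8.0 * math.exp(integral)
        assert cme.distribution_mean(dist.at(t)) == pytest.approx(expected, rel=1e-6)


def test_extinction_state_is_absorbing():
    q0 = np.zeros(6)
    q0[0], q0[5] = 0.5, 0.5
    dist = cme.solve_count_cme(lambda s: 0.0, lambda s: 0.5, q0, [0.0, 30.0], n_max=8, n_max_cap=8)
    qT = dist.at(30.0)
    assert qT[0] == pytest.approx(1.0, abs=1e-6)  # everything dies, mass stays


def test_count_quantiles():
    q = np.zeros((1, 11))
    q[0, 5] = 1.0
    point = cme.CountDistribution(times=np.array([0.0]), q=q)
    assert np.all(cme.count_quantiles(point, 0.0, [0.1, 0.5, 0.9]) == 5)

    b = cme.binomial_initial_distribution(10, 0.5)
    assert cme.count_quantiles(b, 0.0, [0.5])[0] == 5
    with pytest.raises(ValueError):
        cme.count_quantiles(b, 0.0, [1.5])


# --- discrete two-state model -------------------------------------------------

DP = cme.DiscreteModelParams()  # drug-indexed values of the two-state study
ON = TreatmentSchedule.continuous(True)


def test_discrete_mean_counts_no_switching_is_exponential():
    dp = cme.DiscreteModelParams(r01=(0, 0), r10=(0, 0), lam0=(0.2, 0.2), lam1=(0.1, 0.1))
    out = cme.discrete_mean_counts(dp, ON, (5.0, 3.0), [0.0, 2.0])
    assert out[1, 0] == pytest.approx(5 * math.exp(0.4), rel=1e-9)
    assert out[1, 1] == pytest.approx(3 * math.exp(0.2), rel=1e-9)


def test_discrete_long_time_growth_is_dominant_eigenvalue():
    times = np.linspace(0.0, 60.0, 4)
    out = cme.discrete_mean_counts(DP, ON, (10.0, 0.0), times)
    total = out.sum(axis=1)
    growth = (np.log(total[-1]) - np.log(total[-2])) / (times[-1] - times[-2])
    r01, r10, l0, l1 = DP.at(1)
    M = np.array([[l0 - r01, r10], [r01, l1 - r10]])
    lam_max = np.max(np.linalg.eigvals(M).real)
    assert growth == pytest.approx(lam_max, abs=1e-8)


def test_equal_growth_total_independent_of_switching():
    dp_fast = cme.DiscreteModelParams(r01=(2.0, 2.0), r10=(1.0, 1.0), lam0=(0.12, 0.12), lam1=(0.12, 0.12))
    dp_slow = cme.DiscreteModelParams(r01=(0.01, 0.01), r10=(0.02, 0.02), lam0=(0.12, 0.12), lam1=(0.12, 0.12))
    t = [0.0, 5.0]
    tot_fast = cme.discrete_mean_counts(dp_fast, ON, (4.0, 6.0), t)[1].sum()
    tot_slow = cme.discrete_mean_counts(dp_slow, ON, (4.0, 6.0), t)[1].sum()
    assert tot_fast == pytest.approx(10 * math.exp(0.6), rel=1e-9)
    assert tot_slow == pytest.approx(tot_fast, rel=1e-9)


def test_mean_phenotype_coefficients_and_equilibrium():
    A, B, C = cme.discrete_mean_phenotype_coeffs(DP, 1)
    assert (A, B, C) == pytest.approx((1.0, -0.61, -0.4))
    roots = np.roots([C, B, A])
    x_eq = roots[roots > 0][0]
    assert x_eq == pytest.approx(0.9929, abs=5e-4)
    zero = cme.DiscreteModelParams(r01=(0, 0), r10=(0, 0), lam0=(0.1, 0.1), lam1=(0.1, 0.1))
    assert cme.discrete_mean_phenotype_coeffs(zero, 0) == pytest.approx((0, 0, 0))


def test_joint_cme_factorises_without_switching():
    dp = cme.DiscreteModelParams(r01=(0, 0), r10=(0, 0), lam0=(0.12, 0.12), lam1=(-0.2, -0.2))
    init = np.zeros((4, 5))
    init[3, 4] = 1.0
    t = 2.0
    dist, joint = cme.solve_discrete_joint_cme(dp, ON, init, [0.0, t], cap0=40, cap1=20)
    q0a = np.zeros(41); q0a[3] = 1.0
    q0b = np.zeros(21); q0b[4] = 1.0
    sa = cme.solve_count_cme(lambda s: 0.12, lambda s: 0.0, q0a, [0.0, t], n_max=40, n_max_cap=40)
    sb = cme.solve_count_cme(lambda s: 0.0, lambda s: 0.2, q0b, [0.0, t], n_max=20, n_max_cap=20)
    outer = np.outer(sa.at(t), sb.at(t))
    assert np.max(np.abs(joint - outer)) < 1e-7


def test_joint_cme_means_match_mean_odes():
    times = np.array([0.0, 1.0, 3.0, 7.0])
    init = np.zeros((11, 1)); init[10, 0] = 1.0
    dist, _ = cme.solve_discrete_joint_cme(DP, ON, init, times, cap0=60, cap1=120)
    ode = cme.discrete_mean_counts(DP, ON, (10.0, 0.0), times).sum(axis=1)
    for i, t in enumerate(times):
        assert cme.distribution_mean(dist.q[i]) == pytest.approx(ode[i], rel=1e-8)


def test_continuous_equivalent_mean_exact():
    """The quadratic-velocity homogeneous model reproduces the discrete mean
    count exactly, continuous and intermittent treatment alike."""
    times = np.linspace(0.0, 14.0, 29)
    for sched in (ON, TreatmentSchedule.intermittent(period=7.0, t_end=14.0)):
        import dataclasses

        spec = dataclasses.replace(cme.continuous_equivalent(DP), schedule=sched)
        sol = solve_structured_density(spec, (10.0, 0.0, 0.0), times)
        ode = cme.discrete_mean_counts(DP, sched, (10.0, 0.0), times).sum(axis=1)
        assert np.max(np.abs(sol.n_mean - ode) / ode) < 1e-6


def test_continuous_equivalent_no_switching_keeps_lambda_constant():
    dp = cme.DiscreteModelParams(r01=(0, 0), r10=(0, 0), lam0=(0.15, -0.3), lam1=(0.1, 0.1))
    spec = cme.continuous_equivalent(dp)
    sol = solve_structured_density(spec, (1.0, 0.0, 0.0), default_times(5.0))
    assert np.max(np.abs(sol.x_bar)) < 1e-12  # starts sensitive, never switches
    assert sol.n_mean[-1] == pytest.approx(math.exp(-0.3 * 5.0), rel=1e-8)


def test_count_distribution_csv_export(tmp_path):
    import pandas as pd

    dist = cme.binomial_initial_distribution(6, 0.5)
    path = tmp_path / "q.csv"
    dist.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["t", "n", "q"]
    assert len(df) == 7
    assert df.q.sum() == pytest.approx(1.0, abs=1e-12)


def test_discrete_params_json_round_trip():
    dp = cme.DiscreteModelParams()
    assert cme.DiscreteModelParams.from_dict(dp.to_dict()) == dp
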