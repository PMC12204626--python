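"""Likelihoods for counts, event timings, and marker data."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, norm

from phenoadapt import synthetic_data as sd
from phenoadapt.datasets import Condition, CountDataset, EventDataset, MarkerDataset
from phenoadapt.likelihoods import (
    LOG_FLOOR,
    MarkerNoiseParams,
    SolverOptions,
    ThetaVector,
    log_posterior,
    loglik_counts,
    loglik_event_timings,
    loglik_marker,
    marker_density,
    spec_from_params,
)
from phenoadapt.model_core import (
    DiffusionParam,
    GrowthParams,
    ModelSpec,
    TreatmentSchedule,
    VelocityParams,
)
from phenoadapt.pde import default_times, solve_structured_density


def _static_count_dataset(counts, n_well=20, fov=0.4, t=1.0):
    df = pd.DataFrame(
        {
            "condition_id": "sensitive_drug_on",
            "P": 0,
            "schedule_id": "drug_on",
            "t_days": t,
            "replicate": range(len(counts)),
            "count": counts,
        }
    )
    return CountDataset(
        df=df, metadata={"design": {"n_well": n_well, "fov_prob": fov}}
    )


def test_count_likelihood_reduces_to_binomial_without_dynamics(fast_opts):
    """lambda = 0 freezes the count at its field-of-view draw, so each record
    contributes the binomial seeding log-pmf."""
    data = _static_count_dataset([3, 7, 9])
    params = dict(gamma1=0, gamma2=0, gamma3=0, gamma4=0, nu=0.4, beta=0.02)
    ll = loglik_counts(data, params, opts=fast_opts)
    expected = sum(binom.logpmf(n, 20, 0.4) for n in (3, 7, 9))
    assert ll == pytest.approx(expected, abs=1e-6)


def test_count_likelihood_peaks_near_generating_parameters(
    count_data_seed1, true_params, fast_opts
):
    ll_true = loglik_counts(count_data_seed1, true_params, opts=fast_opts)
    ll_pert = loglik_counts(
        count_data_seed1, dict(true_params, gamma1=0.25), opts=fast_opts
    )
    assert ll_true > ll_pert


def test_count_likelihood_invariant_to_record_order(
    count_data_seed1, true_params, fast_opts
):
    shuffled = CountDataset(
        df=count_data_seed1.df.sample(frac=1.0, random_state=0).reset_index(drop=True),
        metadata=count_data_seed1.metadata,
        schedules=count_data_seed1.schedules,
    )
    assert loglik_counts(shuffled, true_params, opts=fast_opts) == pytest.approx(
        loglik_counts(count_data_seed1, true_params, opts=fast_opts), abs=1e-9
    )


def test_simulation_calibration_smoke(true_params, fast_opts, default_spec):
    """Across seeded scaled-down studies the generating parameters beat a
    1.5x-inflated alternative in >= 95% of cases."""
    design = sd.ExperimentDesign(
        conditions=(
            Condition("sensitive_drug_on", 0, "drug_on"),
            Condition("sensitive_drug_off", 0, "drug_off"),
            Condition("resistant_drug_on", 1, "drug_on"),
            Condition("resistant_drug_off", 1, "drug_off"),
        ),
        times=(1.0, 7.0), replicates=12,
    )
    pert = {
        k: (v * 1.5 if k != "beta" else v) for k, v in true_params.items()
    }
    wins = 0
    n_trials = 20
    for seed in range(100, 100 + n_trials):
        data = sd.generate_count_data(design, default_spec, rng_seed=seed)
        if loglik_counts(data, true_params, opts=fast_opts) > loglik_counts(
            data, pert, opts=fast_opts
        ):
            wins += 1
    assert wins >= math.ceil(0.95 * n_trials)


# --- event timings ------------------------------------------------------------


def _event_dataset(rows):
    return EventDataset(
        df=pd.DataFrame(
            rows,
            columns=[
                "bin_start", "bin_end", "n_at_start",
                "n_prolif_events", "n_death_events",
            ],
        )
    )


def test_event_likelihood_zero_events_zero_rates(fast_opts):
    data = _event_dataset([(0.0, 0.5, 100, 0, 0), (0.5, 1.0, 100, 0, 0)])
    params = dict(gamma1=0, gamma2=0, gamma3=0, gamma4=0, nu=0.4, beta=0.02)
    assert loglik_event_timings(data, params, opts=fast_opts) == pytest.approx(0.0, abs=1e-12)


def test_event_likelihood_single_bin_poisson_arithmetic(fast_opts, true_params):
    """One bin: contribution is k log(mu) - mu - log k! with
    mu = r(t_mid) N dt for each channel."""
    data = _event_dataset([(1.0, 1.2, 500, 4, 9)])
    ll = loglik_event_timings(data, true_params, opts=fast_opts)

    spec = spec_from_params(true_params, TreatmentSchedule.continuous(True))
    from phenoadapt.pde import rate_interpolants

    sol = solve_structured_density(
        spec, (1.0, 0.0, 0.05 / math.sqrt(0.8)), default_times(1.2, fast_opts.rate_step),
        grid=fast_opts.grid, dt=fast_opts.pde_dt,
    )
    fp, fd = rate_interpolants(sol)
    mu_p = float(fp(1.1)) * 500 * 0.2
    mu_d = float(fd(1.1)) * 500 * 0.2
    expected = (
        4 * math.log(mu_p) - mu_p - math.log(math.factorial(4))
        + 9 * math.log(mu_d) - mu_d - math.log(math.factorial(9))
    )
    assert ll == pytest.approx(expected, rel=1e-9)


def test_event_likelihood_impossible_data(fast_opts, true_params):
    data = _event_dataset([(0.0, 0.5, 0, 2, 0)])
    assert loglik_event_timings(data, true_params, opts=fast_opts) == -math.inf


def test_event_likelihood_bin_split_shifts_by_constant(fast_opts):
    """With constant rates, splitting a bin changes the log-likelihood only
    by a parameter-independent combinatorial constant, so likelihood
    differences (all that inference uses) are invariant."""
    merged = _event_dataset([(0.0, 1.0, 300, 10, 4)])
    split = _event_dataset([(0.0, 0.5, 300, 6, 1), (0.5, 1.0, 300, 4, 3)])
    p1 = dict(gamma1=0.2, gamma2=0.2, gamma3=0.05, gamma4=0.05, nu=0.4, beta=0.02)
    p2 = dict(gamma1=0.3, gamma2=0.3, gamma3=0.1, gamma4=0.1, nu=0.4, beta=0.02)
    d_merged = loglik_event_timings(merged, p1, opts=fast_opts) - loglik_event_timings(
        merged, p2, opts=fast_opts
    )
    d_split = loglik_event_timings(split, p1, opts=fast_opts) - loglik_event_timings(
        split, p2, opts=fast_opts
    )
    assert d_merged == pytest.approx(d_split, abs=1e-6)


# --- marker data --------------------------------------------------------------


@pytest.fixture(scope="module")
def marker_sol(true_params, fast_opts):
    spec = spec_from_params(true_params, TreatmentSchedule.continuous(True))
    return solve_structured_density(
        spec, (1.0, 0.0, 0.05 / math.sqrt(0.8)), default_times(7.0, fast_opts.rate_step),
        grid=fast_opts.grid, dt=fast_opts.pde_dt,
    )


@pytest.mark.parametrize("noise", [
    MarkerNoiseParams(sigma=0.1, omega=0.0),
    MarkerNoiseParams(sigma=0.15, omega=0.9),
    MarkerNoiseParams(sigma=0.08, omega=-0.6),
])
def test_marker_density_normalised(marker_sol, noise):
    m, dens = marker_density(marker_sol, 3.0, noise)
    assert np.trapezoid(dens, m) == pytest.approx(1.0, abs=1e-4)


def test_translated_gamma_tends_to_gaussian(marker_sol):
    """The skewed noise law converges to the Gaussian as omega -> 0: the
    leading deviation is the O(omega) Edgeworth term, ~1e-4 of the density
    peak at |omega| = 1e-3 on the unit noise scale."""
    from phenoadapt.likelihoods import _noise_logpdf

    e = np.linspace(-6.0, 6.0, 2401)
    gauss = np.exp(_noise_logpdf(e, MarkerNoiseParams(sigma=1.0, omega=0.0)))
    for omega in (1e-3, -1e-3):
        skewed = np.exp(_noise_logpdf(e, MarkerNoiseParams(sigma=1.0, omega=omega)))
        assert np.max(np.abs(gauss - skewed)) < 1e-4

    # and the convolved marker density inherits the convergence (sigma = 0.1
    # rescales the deviation by 1/sigma)
    m, g = marker_density(marker_sol, 3.0, MarkerNoiseParams(sigma=0.1, omega=0.0))
    m2, tg = marker_density(marker_sol, 3.0, MarkerNoiseParams(sigma=0.1, omega=1e-3))
    assert np.max(np.abs(g - np.interp(m, m2, tg))) < 1e-3


def test_marker_density_beta_zero_is_shifted_noise_law(fast_opts):
    """beta = 0, long time, drug on: the marker law is the noise law centred
    on the adapted state."""
    params = dict(gamma1=0.15, gamma2=-0.3, gamma3=0.1, gamma4=0.1, nu=0.4, beta=0.0)
    spec = spec_from_params(params, TreatmentSchedule.continuous(True))
    sol = solve_structured_density(spec, (1.0, 0.0, 0.0), default_times(25.0))
    m, dens = marker_density(sol, 25.0, MarkerNoiseParams(sigma=0.2))
    x_inf = 1 - math.exp(-0.4 * 25)
    assert np.max(np.abs(dens - norm.pdf(m, loc=x_inf, scale=0.2))) < 1e-6


def test_marker_loglik_mode_beats_tail(fast_opts, true_params):
    def dataset(value):
        return MarkerDataset(
            df=pd.DataFrame({"t_days": [7.0], "cell_id": [0], "marker_value": [value]})
        )

    noise = MarkerNoiseParams(sigma=0.1)
    near_mode = loglik_marker(dataset(0.95), true_params, noise, opts=fast_opts)
    far_tail = loglik_marker(dataset(-0.8), true_params, noise, opts=fast_opts)
    assert near_mode > far_tail


def test_marker_loglik_on_generated_data(default_spec, true_params, fast_opts):
    design = sd.ExperimentDesign(
        conditions=(Condition("sensitive_drug_on", 0, "drug_on"),),
        times=(1.0, 7.0), replicates=6,
    )
    noise = MarkerNoiseParams(sigma=0.1)
    data = sd.generate_marker_data(design, default_spec, noise, rng_seed=6)
    ll_true = loglik_marker(data, true_params, noise, opts=fast_opts)
    ll_bad = loglik_marker(
        data, true_params, MarkerNoiseParams(sigma=0.5), opts=fast_opts
    )
    assert math.isfinite(ll_true) and ll_true > ll_bad


# --- posterior plumbing -------------------------------------------------------


def test_theta_vector_transforms_round_trip():
    theta = ThetaVector(free_names=("gamma1", "nu", "beta"), fixed={"gamma2": -0.3})
    params = theta.to_params([0.15, math.log10(0.4), math.log10(0.05)])
    assert params["nu"] == pytest.approx(0.4)
    assert params["beta"] == pytest.approx(0.05)
    assert params["gamma2"] == -0.3
    z = theta.from_params(params)
    assert z == pytest.approx([0.15, math.log10(0.4), math.log10(0.05)])
    with pytest.raises(ValueError):
        ThetaVector(free_names=("nu",), fixed={"nu": 0.4})


def test_log_posterior_uniform_prior(count_theta):
    from phenoadapt.inference import PriorBox

    box = PriorBox()
    ll = lambda p: -0.5 * (p["gamma1"] - 0.1) ** 2
    z_in = count_theta.from_params(
        dict(gamma1=0.1, gamma2=0.0, gamma3=0.0, gamma4=0.0, nu=0.4, beta=0.05)
    )
    z_out = z_in.copy()
    z_out[0] = 5.0  # outside the gamma1 box
    assert log_posterior(z_out, count_theta, box, ll) == -math.inf
    lp1 = log_posterior(z_in, count_theta, box, ll)
    z2 = z_in.copy()
    z2[0] = 0.3
    lp2 = log_posterior(z2, count_theta, box, ll)
    assert lp1 - lp2 == pytest.approx(ll(count_theta.to_params(z_in)) - ll(count_theta.to_params(z2)))
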