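"""Censored-normal mixture likelihood, EM fit, and classification diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

from dditraj.errors import ValidationError
from dditraj.gbtm import (
    GbtmParams,
    Panel,
    TrajectorySpec,
    assign_groups,
    appa,
    bic,
    censored_normal_logdensity,
    entropy,
    fit_gbtm,
    mixture_loglik,
    posterior_probabilities,
    predict_mean_curves,
)
from tests.conftest import included_panel, two_group_config


# ---------------------------------------------------------------------------
# censored likelihood primitive
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("y, mu, sigma, lo, hi, expected", [
    # value at the upper bound with mean on the bound: half the mass is above
    (40.0, 40.0, 1.0, 0.0, 40.0, np.log(0.5)),
    # interior value at the mode of a unit normal
    (5.0, 5.0, 1.0, 0.0, 40.0, -0.9189385332046727),
    # value at the lower bound two SDs below the mean: log Phi(-2)
    (0.0, 2.0, 1.0, 0.0, 40.0, stats.norm.logcdf(-2.0)),
])
def test_censored_logdensity_values(y, mu, sigma, lo, hi, expected):
    assert censored_normal_logdensity(y, mu, sigma, lo, hi) == pytest.approx(
        expected, abs=1e-10)


def test_censored_logdensity_rejects_bad_sigma():
    with pytest.raises(ValidationError):
        censored_normal_logdensity(1.0, 0.0, 0.0, 0.0, 40.0)


def test_censored_logdensity_finite_in_far_tail():
    # a bound observation with the mean far on the other side must stay finite
    val = censored_normal_logdensity(40.0, 1.0, 0.5, 0.0, 40.0)
    assert np.isfinite(val) and val < -100


# ---------------------------------------------------------------------------
# mixture likelihood vs brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_loglik(panel, spec, params):
    """Nested-loop evaluation, independent of the vectorised implementation."""
    total = 0.0
    for i in range(panel.n_subjects):
        mask = panel.subject_index == i
        days, values = panel.day[mask], panel.value[mask]
        per_group = []
        for g in range(spec.n_groups):
            ll = np.log(params.pi[g])
            for d, y in zip(days, values):
                t = d / spec.time_scale
                mu = sum(b * t ** k for k, b in enumerate(params.beta[g]))
                if y <= spec.censor_lo:
                    ll += stats.norm.logcdf((spec.censor_lo - mu) / params.sigma)
                elif y >= spec.censor_hi:
                    ll += stats.norm.logsf((spec.censor_hi - mu) / params.sigma)
                else:
                    ll += stats.norm.logpdf(y, mu, params.sigma)
            per_group.append(ll)
        total += logsumexp(per_group)
    return total


def _tiny_params():
    return GbtmParams(beta=(np.array([1.5, 0.5, -0.1]),
                            np.array([30.0, -2.0, 0.3])),
                      sigma=2.0, pi=np.array([0.55, 0.45]))


def test_mixture_loglik_matches_bruteforce_oracle(tiny_panel):
    spec = TrajectorySpec(2, (2, 2))
    params = _tiny_params()
    assert mixture_loglik(tiny_panel, spec, params) == pytest.approx(
        _oracle_loglik(tiny_panel, spec, params), abs=1e-10)


def test_mixture_loglik_single_group_reduction(tiny_panel):
    spec = TrajectorySpec(1, (2,))
    beta = np.array([1.5, 0.5, -0.1])
    params = GbtmParams(beta=(beta,), sigma=2.0, pi=np.array([1.0]))
    t = tiny_panel.day / spec.time_scale
    mu = beta[0] + beta[1] * t + beta[2] * t ** 2
    direct = censored_normal_logdensity(tiny_panel.value, mu, 2.0, 0.0, 40.0).sum()
    assert mixture_loglik(tiny_panel, spec, params) == pytest.approx(direct)


def test_mixture_loglik_duplicate_components_equal_single(tiny_panel):
    beta = np.array([1.5, 0.5, -0.1])
    one = GbtmParams(beta=(beta,), sigma=2.0, pi=np.array([1.0]))
    dup = GbtmParams(beta=(beta, beta.copy()), sigma=2.0,
                     pi=np.array([0.5, 0.5]))
    assert mixture_loglik(tiny_panel, TrajectorySpec(2, (2, 2)), dup) == \
        pytest.approx(mixture_loglik(tiny_panel, TrajectorySpec(1, (2,)), one),
                      abs=1e-10)


def test_mixture_loglik_label_permutation_invariant(tiny_panel):
    spec = TrajectorySpec(2, (2, 2))
    params = _tiny_params()
    swapped = GbtmParams(beta=params.beta[::-1], sigma=params.sigma,
                         pi=params.pi[::-1])
    assert mixture_loglik(tiny_panel, spec, swapped) == pytest.approx(
        mixture_loglik(tiny_panel, spec, params), abs=1e-10)


def test_censoring_limit_equivalence(tiny_panel):
    # with bounds pushed far out, the Tobit mixture is the plain normal mixture
    spec = TrajectorySpec(2, (2, 2), censor_lo=-1e6, censor_hi=1e6)
    params = _tiny_params()
    t = tiny_panel.day / spec.time_scale
    plain = 0.0
    for i in range(tiny_panel.n_subjects):
        mask = tiny_panel.subject_index == i
        comp = []
        for g in range(2):
            mu = sum(b * t[mask] ** k for k, b in enumerate(params.beta[g]))
            comp.append(np.log(params.pi[g]) + stats.norm.logpdf(
                tiny_panel.value[mask], mu, params.sigma).sum())
        plain += logsumexp(comp)
    assert mixture_loglik(tiny_panel, spec, params) == pytest.approx(
        plain, abs=1e-8)


# ---------------------------------------------------------------------------
# posteriors and assignment
# ---------------------------------------------------------------------------

def test_posterior_identical_components_return_pi(tiny_panel):
    beta = np.array([5.0, 0.0, 0.0])
    params = GbtmParams(beta=(beta, beta.copy()), sigma=1.0,
                        pi=np.array([0.3, 0.7]))
    post = posterior_probabilities(tiny_panel, TrajectorySpec(2, (2, 2)), params)
    assert np.allclose(post, [0.3, 0.7])


def test_posterior_single_group_is_ones(tiny_panel):
    params = GbtmParams(beta=(np.array([5.0, 0.0, 0.0]),), sigma=1.0,
                        pi=np.array([1.0]))
    post = posterior_probabilities(tiny_panel, TrajectorySpec(1, (2,)), params)
    assert np.allclose(post, 1.0)


def test_posterior_matches_logspace_oracle():
    df = pd.DataFrame({"patient_id": [1, 1, 2, 2],
                       "day": [0, 1, 0, 1],
                       "value": [2.0, 3.0, 25.0, 28.0]})
    panel = Panel.from_long(df)
    spec = TrajectorySpec(2, (2, 2))
    params = _tiny_params()
    post = posterior_probabilities(panel, spec, params)
    for i in range(2):
        mask = panel.subject_index == i
        logs = []
        for g in range(2):
            t = panel.day[mask] / spec.time_scale
            mu = sum(b * t ** k for k, b in enumerate(params.beta[g]))
            logs.append(np.log(params.pi[g]) + stats.norm.logpdf(
                panel.value[mask], mu, params.sigma).sum())
        expected = np.exp(logs - logsumexp(logs))
        assert np.allclose(post[i], expected, atol=1e-10)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-8)


def test_assign_groups_argmax_and_tiebreak():
    post = np.array([[0.1, 0.9], [0.5, 0.5], [0.7, 0.3]])
    assert assign_groups(post).tolist() == [1, 0, 0]


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_bic_hand_value():
    assert bic(-100.0, 5, 309) == pytest.approx(-100 - 2.5 * np.log(309))
    assert bic(-100.0, 0, 309) == -100.0


def test_bic_penalty_monotone():
    assert bic(-100.0, 6, 309) < bic(-100.0, 5, 309)


def test_entropy_crisp_uniform_and_hand_value():
    crisp = np.eye(3)[[0, 1, 2, 0]]
    assert entropy(crisp) == pytest.approx(1.0)
    assert entropy(np.full((5, 4), 0.25)) == pytest.approx(0.0)
    rows = np.array([[0.9, 0.1], [0.8, 0.2]])
    assert entropy(rows) == pytest.approx(0.404538, abs=1e-5)
    assert entropy(np.ones((4, 1))) == 1.0   # degenerate one-group convention


def test_appa_hand_values():
    post = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7]])
    labels = assign_groups(post)
    assert np.allclose(appa(post, labels), [0.85, 0.7])
    crisp = np.eye(2)[[0, 1, 0]]
    assert np.allclose(appa(crisp, assign_groups(crisp)), 1.0)
    uniform = np.full((4, 2), 0.5)
    assert np.allclose(appa(uniform, assign_groups(uniform))[0], 0.5)


def test_appa_empty_group_is_nan():
    post = np.array([[0.9, 0.1], [0.8, 0.2]])
    vals = appa(post, np.array([0, 0]))
    assert vals[0] == pytest.approx(0.85)
    assert np.isnan(vals[1])


@settings(derandomize=True, max_examples=30)
@given(st.integers(2, 5), st.integers(2, 30), st.integers(0, 10 ** 6))
def test_entropy_bounds_property(G, n, seed):
    """Relative entropy of any row-stochastic posterior lies in [0, 1]."""
    rng = np.random.default_rng(seed)
    post = rng.dirichlet(np.ones(G) * rng.uniform(0.2, 5.0), size=n)
    e = entropy(post)
    assert -1e-9 <= e <= 1 + 1e-9


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_single_group_matches_polynomial_least_squares():
    rng = np.random.default_rng(5)
    days = np.tile(np.arange(10, dtype=float), 40)
    pid = np.repeat(np.arange(40), 10)
    mu = 10.0 + 0.8 * days - 0.05 * days ** 2
    values = mu + rng.normal(0, 1.0, len(days))   # safely inside (0, 40)
    panel = Panel.from_long(pd.DataFrame(
        {"patient_id": pid, "day": days, "value": values}))
    fit = fit_gbtm(panel, TrajectorySpec(1, (2,)), n_starts=1, seed=0)
    ols = np.polyfit(days, values, 2)[::-1]
    per_day = fit.params.beta_per_day(fit.spec.time_scale)[0]
    assert np.allclose(per_day, ols, rtol=1e-4)


def test_fit_two_group_recovery(two_group_bundle, two_group_panel):
    panel, truth = two_group_panel
    fit = fit_gbtm(panel, TrajectorySpec(2, (2, 2)), n_starts=5, seed=3)
    assert fit.converged
    empirical = np.bincount(truth, minlength=2) / len(truth)
    assert np.all(np.abs(fit.params.pi - empirical) <= 0.05)
    assert (fit.assignment == truth).mean() >= 0.95
    assert abs(fit.params.sigma - 1.5) / 1.5 <= 0.15


def test_fit_tiny_sigma_gives_crisp_entropy():
    bundle_cfg = two_group_config(n=120, sigma=0.1, seed=21)
    from dditraj.synthetic import generate_cohort
    panel, _ = included_panel(generate_cohort(bundle_cfg))
    fit = fit_gbtm(panel, TrajectorySpec(2, (2, 2)), n_starts=4, seed=4)
    assert fit.entropy >= 0.99


def test_fit_em_loglik_monotone(two_group_panel):
    panel, _ = two_group_panel
    fit = fit_gbtm(panel, TrajectorySpec(2, (2, 2)), n_starts=3, seed=9)
    diffs = np.diff(fit.loglik_trace)
    assert np.all(diffs >= -1e-8)


def test_fit_posterior_rows_sum_to_one(two_group_panel):
    panel, _ = two_group_panel
    fit = fit_gbtm(panel, TrajectorySpec(2, (2, 2)), n_starts=3, seed=9)
    assert np.allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(fit.group_props.sum(), 1.0)


def test_single_group_tobit_matches_numeric_oracle():
    """With censored-high values, G=1 ML must match direct optimisation."""
    rng = np.random.default_rng(17)
    days = np.tile(np.arange(8, dtype=float), 50)
    pid = np.repeat(np.arange(50), 8)
    mu = 36.0 + 0.5 * days
    values = np.clip(mu + rng.normal(0, 3.0, len(days)), 0.0, 40.0)
    assert (values >= 40.0).mean() > 0.1
    panel = Panel.from_long(pd.DataFrame(
        {"patient_id": pid, "day": days, "value": values}))
    spec = TrajectorySpec(1, (2,))
    fit = fit_gbtm(panel, spec, n_starts=1, seed=0, tol=1e-10, max_iter=3000)

    t = days / spec.time_scale
    X = np.vander(t, 3, increasing=True)

    def negll(theta):
        beta, log_sigma = theta[:3], theta[3]
        sig = np.exp(log_sigma)
        m = X @ beta
        ll = np.where(values >= 40.0,
                      stats.norm.logsf((40.0 - m) / sig),
                      stats.norm.logpdf(values, m, sig))
        return -ll.sum()

    res = minimize(negll, np.array([30.0, 0.0, 0.0, 1.0]), method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    assert fit.loglik == pytest.approx(-res.fun, rel=1e-4)


def test_fit_relabels_groups_low_to_high(two_group_panel):
    panel, _ = two_group_panel
    fit = fit_gbtm(panel, TrajectorySpec(2, (2, 2)), n_starts=4, seed=2)
    assert fit.params.beta[0][0] < fit.params.beta[1][0]


# ---------------------------------------------------------------------------
# mean curves
# ---------------------------------------------------------------------------

def test_predict_mean_curves_flat_and_clipped():
    spec = TrajectorySpec(2, (2, 2))
    params = GbtmParams(beta=(np.array([5.0, 0.0, 0.0]),
                              np.array([45.0, 0.0, 0.0])),
                        sigma=1.0, pi=np.array([0.5, 0.5]))
    table = predict_mean_curves(params, spec)
    g1 = table[table["group"] == 1]
    g2 = table[table["group"] == 2]
    assert len(g1) == 51 and len(g2) == 51
    assert np.allclose(g1["mean"], 5.0)
    assert np.allclose(g2["mean"], 40.0)       # displayed at the bound
    assert np.allclose(g2["latent_mean"], 45.0)
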