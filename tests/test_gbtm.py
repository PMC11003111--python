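"""Censored-normal trajectory mixture: likelihoods, EM, selection, posteriors."""

import math

import numpy as np
import pandas as pd
import pytest

import adhertraj as at
from adhertraj.gbtm import censored_normal_mean, cnorm_obs_loglik


def _panel(y, pids=None):
    """Long panel from an (n, T) array of PDC values."""
    y = np.asarray(y, dtype=float)
    n, T = y.shape
    if pids is None:
        pids = [f"P{i}" for i in range(n)]
    return pd.DataFrame({
        "patient_id": np.repeat(pids, T),
        "t": np.tile(np.arange(T), n),
        "covered_days": np.round(y.ravel() * 182).astype(int),
        "denominator_days": 182,
        "pdc": y.ravel(),
    })


# ---------------------------------------------------------------------------
# censored-normal observation likelihood
# ---------------------------------------------------------------------------

def _phi_cdf(x):
    """Standard normal CDF via the error function (independent oracle)."""
    return 0.5 * math.erfc(-x / math.sqrt(2))


@pytest.mark.parametrize(
    "y,mu,sigma,expected",
    [
        # boundary symmetry: P(Y* >= 1 | mu=1) = 1/2
        (1.0, 1.0, 0.2, math.log(0.5)),
        # interior: standard normal density at 0 scaled by 1/sigma
        (0.5, 0.5, 0.2, math.log(1.0 / (0.2 * math.sqrt(2 * math.pi)))),
        # lower censoring two SDs below the mean
        (0.0, 0.3, 0.15, math.log(_phi_cdf(-2.0))),
    ],
)
def test_cnorm_obs_loglik_values(y, mu, sigma, expected):
    assert cnorm_obs_loglik(y, mu, sigma) == pytest.approx(expected, rel=1e-12)


def test_cnorm_obs_loglik_domain_errors():
    with pytest.raises(ValueError):
        cnorm_obs_loglik(1.5, 0.5, 0.2)
    with pytest.raises(ValueError):
        cnorm_obs_loglik(0.5, 0.5, 0.0)


# ---------------------------------------------------------------------------
# mixture likelihood
# ---------------------------------------------------------------------------

def _brute_force_mixture_loglik(y, s, pi, betas, sigma):
    """Direct enumeration with math-library scalars (independent oracle)."""
    total = 0.0
    for yi, si in zip(y, s):
        patient = 0.0
        for p, beta in zip(pi, betas):
            prod = 1.0
            for yt, st_ in zip(yi, si):
                mu = sum(b * st_**k for k, b in enumerate(beta))
                if yt <= 0.0:
                    lik = _phi_cdf((0.0 - mu) / sigma)
                elif yt >= 1.0:
                    lik = 1.0 - _phi_cdf((1.0 - mu) / sigma)
                else:
                    z = (yt - mu) / sigma
                    lik = math.exp(-0.5 * z * z) / (sigma * math.sqrt(2 * math.pi))
                prod *= lik
            patient += p * prod
        total += math.log(patient)
    return total


def test_mixture_loglik_matches_brute_force_enumeration():
    """3 patients x 2 intervals, fixed parameters, censored and interior
    values: the vectorized likelihood equals direct enumeration to 1e-10."""
    y = np.array([[1.0, 0.8], [0.5, 0.0], [0.9, 0.7]])
    panel = _panel(y)
    model = at.TrajectoryModel(
        J=2, orders=(1, 2), beta=[np.array([0.9, -0.1]), np.array([0.5, -0.3, 0.1])],
        sigma=0.2, pi=np.array([0.6, 0.4]), loglik=np.nan, n_patients=3,
        converged=True, n_restarts_used=0, time_denom=1,
    )
    got = at.mixture_loglik(panel, model)
    s = np.array([[0.0, 1.0]] * 3)
    want = _brute_force_mixture_loglik(y, s, model.pi, model.beta, model.sigma)
    assert got == pytest.approx(want, rel=1e-10)


def test_mixture_loglik_single_group_reduces_to_sum():
    y = np.array([[0.3, 0.7], [1.0, 0.2]])
    panel = _panel(y)
    beta = np.array([0.6, -0.2])
    model = at.TrajectoryModel(
        J=1, orders=(1,), beta=[beta], sigma=0.25, pi=np.array([1.0]),
        loglik=np.nan, n_patients=2, converged=True, n_restarts_used=0, time_denom=1,
    )
    s = np.array([0.0, 1.0, 0.0, 1.0])
    mu = beta[0] + beta[1] * s
    want = cnorm_obs_loglik(y.ravel(), mu, 0.25).sum()
    assert at.mixture_loglik(panel, model) == pytest.approx(want, rel=1e-12)


def test_mixture_loglik_identical_groups_is_noop():
    y = np.array([[0.3, 0.7], [1.0, 0.2], [0.6, 0.6]])
    panel = _panel(y)
    beta = np.array([0.6, -0.2])
    one = at.TrajectoryModel(
        J=1, orders=(1,), beta=[beta], sigma=0.25, pi=np.array([1.0]),
        loglik=np.nan, n_patients=3, converged=True, n_restarts_used=0, time_denom=1,
    )
    two = at.TrajectoryModel(
        J=2, orders=(1, 1), beta=[beta, beta.copy()], sigma=0.25,
        pi=np.array([0.5, 0.5]), loglik=np.nan, n_patients=3, converged=True,
        n_restarts_used=0, time_denom=1,
    )
    assert at.mixture_loglik(panel, two) == pytest.approx(
        at.mixture_loglik(panel, one), rel=1e-12
    )


def test_label_permutation_invariance(fitted_3group):
    _, panel, _, model = fitted_3group
    perm = [2, 0, 1]
    permuted = at.TrajectoryModel(
        J=3, orders=tuple(model.orders[i] for i in perm),
        beta=[model.beta[i] for i in perm], sigma=model.sigma,
        pi=model.pi[perm], loglik=model.loglik, n_patients=model.n_patients,
        converged=True, n_restarts_used=0, time_denom=model.time_denom,
    )
    assert at.mixture_loglik(panel, permuted) == pytest.approx(model.loglik, rel=1e-9)
    assert at.bic(permuted) == pytest.approx(at.bic(model), rel=1e-9)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_j1_interior_fit_equals_least_squares():
    """With no censored observations the censored-normal ML estimate for a
    single group is the ordinary least-squares line and the ML residual SD."""
    rng = np.random.default_rng(4)
    n, T = 120, 6
    s = np.arange(T) / (T - 1)
    y = np.clip(0.6 - 0.15 * s + rng.normal(0, 0.05, (n, T)), 0.05, 0.95)
    assert (y > 0).all() and (y < 1).all()
    panel = _panel(y)
    model = at.fit_gbtm(panel, 1, 1, seed=0, n_restarts=1)
    X = np.column_stack([np.ones(n * T), np.tile(s, n)])
    beta_ols, *_ = np.linalg.lstsq(X, y.ravel(), rcond=None)
    resid = y.ravel() - X @ beta_ols
    sigma_ml = np.sqrt(np.mean(resid**2))
    np.testing.assert_allclose(model.beta[0], beta_ols, atol=1e-6)
    assert model.sigma == pytest.approx(sigma_ml, abs=1e-6)


def test_em_loglik_monotone(fitted_3group):
    _, _, _, model = fitted_3group
    increments = np.diff(model.loglik_trace)
    assert increments.min() > -1e-6


def test_parameter_recovery_three_groups(fitted_3group):
    """pi and group mean curves recovered from data simulated under the
    default 3-group model (single-seed spot check; the multi-seed version
    lives in the acceptance suite)."""
    cfg, panel, truth, model = fitted_3group
    np.testing.assert_allclose(model.pi, cfg.group_mixing, atol=0.03)
    t_grid = np.arange(cfg.n_intervals)
    s = t_grid / (cfg.n_intervals - 1)
    for j, coefs in enumerate(cfg.group_polynomials):
        mu_true = sum(c * s**p for p, c in enumerate(coefs))
        true_curve = censored_normal_mean(mu_true, cfg.sigma)
        fit_curve = censored_normal_mean(model.mean_curve(j, t_grid), model.sigma)
        np.testing.assert_allclose(fit_curve, true_curve, atol=0.05)


def test_fit_rejects_bad_arguments(recovery_panel):
    _, panel, _ = recovery_panel
    with pytest.raises(ValueError):
        at.fit_gbtm(panel, 2, (2,), seed=0)
    with pytest.raises(ValueError):
        at.fit_gbtm(panel, 1, 3, seed=0)
    with pytest.raises(ValueError):
        at.fit_gbtm(panel.iloc[0:0], 1, 0, seed=0)


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def test_bic_arithmetic():
    model = at.TrajectoryModel(
        J=2, orders=(1, 0), beta=[np.zeros(2), np.zeros(1)], sigma=0.1,
        pi=np.array([0.5, 0.5]), loglik=-100.0, n_patients=100,
        converged=True, n_restarts_used=0, time_denom=1,
    )
    # k = (2 + 1) + (J-1) + 1 = 5
    assert model.k_params == 5
    assert at.bic(model) == pytest.approx(-100 - 0.5 * 5 * math.log(100))


def test_bic_penalty_monotone():
    base = dict(beta=[np.zeros(1)], sigma=0.1, pi=np.array([1.0]), loglik=-50.0,
                n_patients=80, converged=True, n_restarts_used=0, time_denom=1)
    m0 = at.TrajectoryModel(J=1, orders=(0,), **base)
    base1 = dict(base, beta=[np.zeros(2)])
    m1 = at.TrajectoryModel(J=1, orders=(1,), **base1)
    assert at.bic(m1) < at.bic(m0)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_select_model_single_candidate(recovery_panel):
    _, panel, _ = recovery_panel
    model, trace = at.select_model(panel, j_range=[3], seed=5, n_restarts=1)
    assert model.J == 3
    assert len([r for r in trace.step1 if "error" not in r]) == 1
    assert trace.chosen["J"] == 3


def test_select_model_bookkeeping(recovery_panel):
    _, panel, _ = recovery_panel
    model, trace = at.select_model(panel, j_range=[2, 3], seed=5, n_restarts=1)
    assert len(trace.step1) == 2
    assert trace.chosen is not None
    assert any(r["J"] == model.J for r in trace.step1)


# ---------------------------------------------------------------------------
# posteriors and diagnostics
# ---------------------------------------------------------------------------

def test_posterior_single_group_is_one(recovery_panel):
    _, panel, _ = recovery_panel
    model = at.fit_gbtm(panel, 1, 1, seed=0, n_restarts=1)
    out = at.posterior_assign(model, panel)
    assert (out["posterior_1"] == 1.0).all()
    assert (out["assigned_group"] == 1).all()


def test_posterior_symmetric_tie_breaks_low():
    """A patient equidistant from two symmetric groups gets posterior 1/2
    each and is assigned to group 1."""
    y = np.array([[0.5, 0.5]])
    panel = _panel(y)
    model = at.TrajectoryModel(
        J=2, orders=(0, 0), beta=[np.array([0.6]), np.array([0.4])], sigma=0.2,
        pi=np.array([0.5, 0.5]), loglik=np.nan, n_patients=1, converged=True,
        n_restarts_used=0, time_denom=1,
    )
    out = at.posterior_assign(model, panel)
    assert out["posterior_1"].iloc[0] == pytest.approx(0.5, abs=1e-12)
    assert out["assigned_group"].iloc[0] == 1


def test_posterior_matches_hand_computed_bayes_ratio():
    y = np.array([[0.9, 0.2]])
    panel = _panel(y)
    b1, b2 = np.array([0.9]), np.array([0.3])
    sigma, pi = 0.2, np.array([0.7, 0.3])
    model = at.TrajectoryModel(
        J=2, orders=(0, 0), beta=[b1, b2], sigma=sigma, pi=pi, loglik=np.nan,
        n_patients=1, converged=True, n_restarts_used=0, time_denom=1,
    )
    l1 = np.exp(cnorm_obs_loglik(0.9, 0.9, sigma) + cnorm_obs_loglik(0.2, 0.9, sigma))
    l2 = np.exp(cnorm_obs_loglik(0.9, 0.3, sigma) + cnorm_obs_loglik(0.2, 0.3, sigma))
    want = pi[0] * l1 / (pi[0] * l1 + pi[1] * l2)
    out = at.posterior_assign(model, panel)
    assert out["posterior_1"].iloc[0] == pytest.approx(want, rel=1e-10)
    assert out["posterior_1"].iloc[0] + out["posterior_2"].iloc[0] == pytest.approx(1.0)


def test_diagnostics_separated_groups(fitted_3group):
    _, panel, _, model = fitted_3group
    assign = at.posterior_assign(model, panel)
    diag = at.diagnostics(model, assign, panel=panel)
    assert (diag.appa >= 0.7).all()
    assert diag.shares.sum() == pytest.approx(1.0)
    assert diag.spaghetti is not None
    assert set(diag.spaghetti["assigned_group"]) <= {1, 2, 3}


def test_occ_identity_uninformative_posteriors():
    """If APPA_j equals pi_j the odds of correct classification are 1."""
    model = at.TrajectoryModel(
        J=2, orders=(0, 0), beta=[np.array([0.6]), np.array([0.4])], sigma=0.2,
        pi=np.array([0.6, 0.4]), loglik=np.nan, n_patients=10, converged=True,
        n_restarts_used=0, time_denom=1,
    )
    assign = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(10)],
        "assigned_group": [1] * 6 + [2] * 4,
        "max_posterior": [0.6] * 6 + [0.4] * 4,
    })
    diag = at.diagnostics(model, assign)
    np.testing.assert_allclose(diag.occ, [1.0, 1.0], rtol=1e-12)


# ---------------------------------------------------------------------------
# predicted trajectory
# ---------------------------------------------------------------------------

def test_predicted_mean_degenerate_noise():
    assert censored_normal_mean(0.5, 1e-9) == pytest.approx(0.5, abs=1e-9)
    assert censored_normal_mean(2.0, 0.1) == pytest.approx(1.0, abs=1e-12)


def test_predicted_mean_matches_monte_carlo():
    """Closed-form censored mean vs a large simulation of clip(Y*, 0, 1)."""
    rng = np.random.default_rng(99)
    draws = np.clip(rng.normal(0.5, 0.5, size=2_000_000), 0, 1)
    mc, se = draws.mean(), draws.std() / np.sqrt(draws.size)
    assert censored_normal_mean(0.5, 0.5) == pytest.approx(mc, abs=3 * se)


def test_predicted_trajectory_with_ci(fitted_3group):
    _, panel, _, model = fitted_3group
    pred = at.predicted_trajectory(model, 0, np.arange(9), panel=panel)
    assert (pred["ci_low"] <= pred["mean_pdc"]).all()
    assert (pred["mean_pdc"] <= pred["ci_high"]).all()
    assert pred["mean_pdc"].between(0, 1).all()
    with pytest.raises(ValueError):
        at.predicted_trajectory(model, 5, np.arange(9))
    with pytest.warns(UserWarning, match="extrapolating"):
        at.predicted_trajectory(model, 0, np.array([40.0]))
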