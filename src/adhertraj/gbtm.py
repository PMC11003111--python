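"""Censored-normal group-based trajectory modeling (GBTM) for PDC panels.

A finite mixture in which each latent group j has a polynomial mean
trajectory mu_j(s) = x(s)' beta_j on scaled interval time s in [0, 1], a
shared residual SD sigma, and the observed proportion of days covered
(PDC) follows a normal distribution censored at the interval bounds
[0, 1]:

    y = 0         contributes  log Phi((0 - mu) / sigma)
    y = 1         contributes  log(1 - Phi((1 - mu) / sigma))
    0 < y < 1     contributes  log phi((y - mu) / sigma) - log sigma

Fitting is by EM on the latent group indicator with a quasi-Newton M-step;
model selection follows a three-step protocol: (1) choose the number of
groups by BIC among all-quadratic models, (2) prune polynomial orders by
Wald tests on the highest-order terms, (3) posterior diagnostics (APPA,
OCC, group shares).  BIC uses the Nagin convention loglik - (k/2) ln n,
larger is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm


# ---------------------------------------------------------------------------
# observation model
# ---------------------------------------------------------------------------

def cnorm_obs_loglik(y, mu, sigma, lower: float = 0.0, upper: float = 1.0):
    """Log-density contribution of one censored-normal observation.

    Vectorized over ``y`` and ``mu``.  Values exactly at the bounds are
    treated as censored (tail probability); interior values contribute the
    Gaussian density.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < lower) or np.any(y > upper):
        raise ValueError("y must lie within the censoring bounds")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    y, mu = np.broadcast_arrays(y, mu)
    out = np.empty(y.shape, dtype=float)
    at_lo = y <= lower
    at_hi = y >= upper
    interior = ~(at_lo | at_hi)
    out[at_lo] = log_ndtr((lower - mu[at_lo]) / sigma)
    out[at_hi] = log_ndtr((mu[at_hi] - upper) / sigma)
    z = (y[interior] - mu[interior]) / sigma
    out[interior] = -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    return out if out.shape else float(out)


def _cnorm_ll_grad(y, mu, sigma, masks):
    """(ll, dll/dmu, dll/dsigma) per observation, reusing bound masks."""
    at_lo, at_hi, interior = masks
    ll = np.empty_like(y)
    dmu = np.empty_like(y)
    dsig = np.empty_like(y)

    a = (0.0 - mu[at_lo]) / sigma
    la = log_ndtr(a)
    ratio = np.exp(norm.logpdf(a) - la)  # phi/Phi, stable in the tail
    ll[at_lo] = la
    dmu[at_lo] = -ratio / sigma
    dsig[at_lo] = -a * ratio / sigma

    b = (mu[at_hi] - 1.0) / sigma
    lb = log_ndtr(b)
    ratio_b = np.exp(norm.logpdf(b) - lb)
    ll[at_hi] = lb
    dmu[at_hi] = ratio_b / sigma
    dsig[at_hi] = -b * ratio_b / sigma

    z = (y[interior] - mu[interior]) / sigma
    ll[interior] = -0.5 * z * z - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    dmu[interior] = z / sigma
    dsig[interior] = (z * z - 1.0) / sigma
    return ll, dmu, dsig


def censored_normal_mean(mu, sigma):
    """E[min(1, max(0, Y))] for Y ~ N(mu, sigma^2), in closed form."""
    mu = np.asarray(mu, dtype=float)
    a = (0.0 - mu) / sigma
    b = (1.0 - mu) / sigma
    return (
        1.0 - norm.cdf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sigma * (norm.pdf(a) - norm.pdf(b))
    )


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass
class _PanelData:
    """Stacked long-format panel prepared for vectorized likelihoods."""

    y: np.ndarray           # (N_obs,) PDC values in [0,1]
    basis: np.ndarray       # (N_obs, 3) columns 1, s, s^2
    pat_idx: np.ndarray     # (N_obs,) patient index 0..n-1
    patient_ids: np.ndarray  # (n,)
    time_denom: int         # t scaling divisor (max interval index)
    masks: tuple            # (at 0, at 1, interior)

    @property
    def n(self) -> int:
        return len(self.patient_ids)


def _prepare(panel: pd.DataFrame, time_denom: int | None = None) -> _PanelData:
    if len(panel) == 0:
        raise ValueError("empty panel set")
    df = panel.sort_values(["patient_id", "t"], kind="mergesort")
    ids, pat_idx = np.unique(df["patient_id"].to_numpy(), return_inverse=True)
    counts = np.bincount(pat_idx)
    if counts.min() < 2:
        raise ValueError("every panel must have at least 2 intervals")
    t = df["t"].to_numpy(dtype=float)
    if time_denom is None:
        time_denom = int(max(t.max(), 1))
    s = t / time_denom
    y = np.clip(df["pdc"].to_numpy(dtype=float), 0.0, 1.0)
    basis = np.column_stack([np.ones_like(s), s, s * s])
    at_lo = y <= 0.0
    at_hi = y >= 1.0
    return _PanelData(y, basis, pat_idx, ids, time_denom, (at_lo, at_hi, ~(at_lo | at_hi)))


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryModel:
    """Fitted J-group censored-normal polynomial mixture."""

    J: int
    orders: tuple[int, ...]
    beta: list[np.ndarray]          # per-group coefficients, length d_j + 1
    sigma: float
    pi: np.ndarray                  # mixing proportions
    loglik: float
    n_patients: int
    converged: bool
    n_restarts_used: int
    time_denom: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    bounds: tuple[float, float] = (0.0, 1.0)
    _param_cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def k_params(self) -> int:
        return sum(d + 1 for d in self.orders) + (self.J - 1) + 1

    def mean_curve(self, group: int, t_grid: np.ndarray) -> np.ndarray:
        """Latent (uncensored) polynomial mean for one group, t in interval units."""
        s = np.asarray(t_grid, dtype=float) / self.time_denom
        b = self.beta[group]
        return sum(c * s**p for p, c in enumerate(b))

    def to_dict(self) -> dict:
        return {
            "J": self.J,
            "orders": list(self.orders),
            "beta": [b.tolist() for b in self.beta],
            "sigma": self.sigma,
            "pi": self.pi.tolist(),
            "loglik": self.loglik,
            "bic": bic(self),
            "n_patients": self.n_patients,
            "k_params": self.k_params,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "time_denom": self.time_denom,
        }


@dataclass
class SelectionTrace:
    """Candidate models examined during the 3-step selection protocol."""

    step1: list[dict] = field(default_factory=list)
    step2: list[dict] = field(default_factory=list)
    chosen: dict | None = None


@dataclass
class Diagnostics:
    """Post-selection adequacy measures for the chosen model."""

    appa: np.ndarray          # average posterior probability of assignment
    occ: np.ndarray           # odds of correct classification
    shares: np.ndarray        # assigned-group shares
    flagged: np.ndarray       # groups with APPA < threshold (or empty)
    appa_threshold: float
    spaghetti: pd.DataFrame | None = None   # per-patient series keyed by group


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _patient_group_ll(data: _PanelData, beta, orders, sigma) -> np.ndarray:
    """(n, J) matrix of per-patient conditional log-likelihoods."""
    J = len(beta)
    L = np.empty((data.n, J))
    for j in range(J):
        mu = data.basis[:, : orders[j] + 1] @ beta[j]
        ll = cnorm_obs_loglik(data.y, mu, sigma)
        L[:, j] = np.bincount(data.pat_idx, weights=ll, minlength=data.n)
    return L


def _mixture_loglik(data: _PanelData, beta, orders, sigma, pi) -> float:
    L = _patient_group_ll(data, beta, orders, sigma)
    return float(logsumexp(np.log(pi) + L, axis=1).sum())


def mixture_loglik(panel: pd.DataFrame, model: TrajectoryModel) -> float:
    """Total mixture log-likelihood of a PDC panel under a fitted model."""
    data = _prepare(panel, time_denom=model.time_denom)
    return _mixture_loglik(data, model.beta, model.orders, model.sigma, model.pi)


def _pack(beta, sigma):
    return np.concatenate([np.concatenate(beta), [np.log(sigma)]])


def _unpack(theta, orders):
    beta = []
    pos = 0
    for d in orders:
        beta.append(theta[pos : pos + d + 1])
        pos += d + 1
    return beta, float(np.exp(theta[-1]))


def _neg_q(theta, data: _PanelData, W_obs: np.ndarray, orders):
    """Negative expected complete-data loglik and its gradient."""
    beta, sigma = _unpack(theta, orders)
    total = 0.0
    grad = np.zeros_like(theta)
    pos = 0
    g_logsig = 0.0
    for j, d in enumerate(orders):
        X = data.basis[:, : d + 1]
        mu = X @ beta[j]
        ll, dmu, dsig = _cnorm_ll_grad(data.y, mu, sigma, data.masks)
        w = W_obs[:, j]
        total += w @ ll
        grad[pos : pos + d + 1] = X.T @ (w * dmu)
        g_logsig += (w @ dsig) * sigma
        pos += d + 1
    grad[-1] = g_logsig
    return -total, -grad


def _m_step(data, W, orders, theta0):
    """Maximize Q over (beta, log sigma); never returns a worse point."""
    W_obs = W[data.pat_idx]
    # generalized EM: a partial M-step that improves Q preserves ascent,
    # so the inner optimizer is capped for speed
    res = optimize.minimize(
        _neg_q, theta0, args=(data, W_obs, orders), jac=True, method="L-BFGS-B",
        options={"maxiter": 15, "ftol": 1e-11, "gtol": 1e-6},
    )
    f0, _ = _neg_q(theta0, data, W_obs, orders)
    return res.x if res.fun <= f0 else theta0


def _initial_fit(data: _PanelData, J, orders, rng, perturb: bool):
    """Quantile-split initialization on patient-mean PDC."""
    pat_mean = np.bincount(data.pat_idx, weights=data.y) / np.bincount(data.pat_idx)
    order_idx = np.argsort(-pat_mean, kind="mergesort")  # descending mean
    strata = np.empty(data.n, dtype=int)
    for j, chunk in enumerate(np.array_split(order_idx, J)):
        strata[chunk] = j
    if perturb:
        flip = rng.random(data.n) < 0.10
        strata[flip] = rng.integers(0, J, size=flip.sum())
    beta = []
    resid_ss, resid_n = 0.0, 0
    for j, d in enumerate(orders):
        sel = strata[data.pat_idx] == j
        X = data.basis[sel, : d + 1]
        yy = data.y[sel]
        if len(yy) <= d + 1:
            b = np.zeros(d + 1)
            b[0] = 0.5
        else:
            b, *_ = np.linalg.lstsq(X, yy, rcond=None)
            resid_ss += float(((yy - X @ b) ** 2).sum())
            resid_n += len(yy)
        beta.append(b)
    sigma = max(np.sqrt(resid_ss / max(resid_n, 1)), 0.02)
    if perturb:
        beta = [b + rng.normal(0.0, 0.05, size=b.shape) for b in beta]
    pi = np.bincount(strata, minlength=J).astype(float)
    pi = np.maximum(pi, 1.0)
    pi /= pi.sum()
    return beta, sigma, pi


def _full_neg_loglik_grad(theta, data: _PanelData, orders, J):
    """Negative mixture loglik and gradient over the full parameter vector
    (stacked betas, J-1 mixing logits, log sigma).

    Uses the identity that the score of the observed-data likelihood equals
    the posterior-weighted complete-data score.
    """
    n_beta = sum(d + 1 for d in orders)
    beta, pos = [], 0
    for d in orders:
        beta.append(theta[pos : pos + d + 1])
        pos += d + 1
    logits = np.concatenate([theta[n_beta : n_beta + J - 1], [0.0]])
    pi = np.exp(logits - logsumexp(logits))
    sigma = float(np.exp(theta[-1]))

    ll_obs = np.empty((len(data.y), J))
    dmu_obs = np.empty_like(ll_obs)
    dsig_obs = np.empty_like(ll_obs)
    for j in range(J):
        mu = data.basis[:, : orders[j] + 1] @ beta[j]
        ll_obs[:, j], dmu_obs[:, j], dsig_obs[:, j] = _cnorm_ll_grad(
            data.y, mu, sigma, data.masks
        )
    L = np.empty((data.n, J))
    for j in range(J):
        L[:, j] = np.bincount(data.pat_idx, weights=ll_obs[:, j], minlength=data.n)
    log_num = np.log(pi) + L
    lse = logsumexp(log_num, axis=1)
    total = float(lse.sum())
    W = np.exp(log_num - lse[:, None])
    W_obs = W[data.pat_idx]

    grad = np.zeros_like(theta)
    pos = 0
    for j, d in enumerate(orders):
        grad[pos : pos + d + 1] = data.basis[:, : d + 1].T @ (W_obs[:, j] * dmu_obs[:, j])
        pos += d + 1
    if J > 1:
        grad[n_beta : n_beta + J - 1] = (W.sum(axis=0) - data.n * pi)[:-1]
    grad[-1] = float((W_obs * dsig_obs).sum()) * sigma
    return -total, -grad


def _polish(data, J, orders, beta, sigma, pi, tol):
    """Direct quasi-Newton maximization of the mixture loglik.

    Run in rounds; converged when a further round improves the loglik by
    less than ``tol`` relative, or the optimizer reports stationarity.
    """
    logits = np.log(np.maximum(pi, 1e-12)) - np.log(max(pi[-1], 1e-12))
    theta = np.concatenate([np.concatenate(beta), logits[:-1], [np.log(sigma)]])
    prev = np.inf
    ok = False
    for _ in range(4):
        res = optimize.minimize(
            _full_neg_loglik_grad, theta, args=(data, orders, J), jac=True,
            method="L-BFGS-B", options={"maxiter": 400, "ftol": 1e-13, "gtol": 1e-7},
        )
        theta = res.x
        if res.success or (prev - res.fun) < tol * (abs(res.fun) + 1.0):
            ok = True
            break
        prev = res.fun
    n_beta = sum(d + 1 for d in orders)
    beta, pos = [], 0
    for d in orders:
        beta.append(theta[pos : pos + d + 1])
        pos += d + 1
    logits = np.concatenate([theta[n_beta : n_beta + J - 1], [0.0]])
    pi = np.exp(logits - logsumexp(logits))
    sigma = float(np.exp(theta[-1]))
    return beta, sigma, pi, -res.fun, bool(res.success)


def _em_run(data, J, orders, beta, sigma, pi, tol, max_iter, em_iter_cap=30):
    """EM ascent followed by a direct quasi-Newton polish.

    EM iterates until the relative loglik change drops below a hand-off
    threshold (or ``em_iter_cap``); remaining slow progress along flat
    likelihood ridges is finished by L-BFGS on the full parameter vector,
    which preserves monotonicity because it starts from the EM iterate and
    is only accepted when it improves.
    """
    theta = _pack(beta, sigma)
    trace = []
    prev = -np.inf
    converged = False
    degenerate = False
    handoff = max(tol, 1e-7)
    for _ in range(min(max_iter, em_iter_cap)):
        beta, sigma = _unpack(theta, orders)
        L = _patient_group_ll(data, beta, orders, sigma)
        log_num = np.log(pi) + L
        ll = float(logsumexp(log_num, axis=1).sum())
        trace.append(ll)
        W = np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))
        pi = W.mean(axis=0)
        if np.any(pi < 1.0 / data.n):
            degenerate = True
            break
        if prev > -np.inf and (ll - prev) < handoff * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
        theta = _m_step(data, W, orders, theta)
    beta, sigma = _unpack(theta, orders)
    em_ll = _mixture_loglik(data, beta, orders, sigma, pi)
    trace.append(em_ll)
    if not degenerate:
        pb, ps, pp, pll, ok = _polish(data, J, orders, beta, sigma, pi, tol)
        if pll >= em_ll and np.all(pp >= 1.0 / (2 * data.n)):
            beta, sigma, pi = pb, ps, pp
            trace.append(pll)
            converged = ok or converged or (pll - em_ll) < tol * (abs(em_ll) + 1.0)
    final_ll = _mixture_loglik(data, beta, orders, sigma, pi)
    return beta, sigma, pi, final_ll, np.array(trace), converged, degenerate


def fit_gbtm(
    panel: pd.DataFrame,
    J: int,
    orders,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    time_denom: int | None = None,
) -> TrajectoryModel:
    """Fit a J-group censored-normal trajectory mixture by multi-start EM.

    Parameters
    ----------
    panel
        Long-format PDC panel with columns patient_id, t, pdc.
    J
        Number of latent groups.
    orders
        Per-group polynomial degree, each in {0, 1, 2}; an int applies the
        same degree to every group.
    seed, n_restarts
        The first start uses a deterministic quantile-split initialization;
        subsequent restarts perturb coefficients and initial memberships.

    Returns the restart with the highest log-likelihood, with groups
    relabeled in descending order of mean fitted trajectory (group 0 =
    highest adherence).
    """
    if np.isscalar(orders):
        orders = (int(orders),) * J
    orders = tuple(int(d) for d in orders)
    if J < 1 or len(orders) != J or any(d not in (0, 1, 2) for d in orders):
        raise ValueError("J must be >= 1 and orders must be length J with values in {0,1,2}")
    data = _prepare(panel, time_denom=time_denom)
    rng = np.random.default_rng(seed)

    best = None
    used = 0
    for r in range(max(n_restarts, 1)):
        used = r + 1
        beta0, sigma0, pi0 = _initial_fit(data, J, orders, rng, perturb=r > 0)
        beta, sigma, pi, ll, trace, conv, degen = _em_run(
            data, J, orders, beta0, sigma0, pi0, tol, max_iter
        )
        if degen:
            continue
        if best is None or ll > best[3]:
            best = (beta, sigma, pi, ll, trace, conv)
        if conv and r == 0 and J == 1:
            break
    if best is None:
        # all restarts collapsed a group; return the last run, flagged
        best = (beta, sigma, pi, ll, trace, False)
    beta, sigma, pi, ll, trace, conv = best

    # canonical label order: descending mean trajectory over the fitted window
    grid = np.linspace(0, 1, 21)
    means = [
        float(np.mean(censored_normal_mean(sum(c * grid**p for p, c in enumerate(b)), sigma)))
        for b in beta
    ]
    order_ix = np.argsort(-np.asarray(means), kind="mergesort")
    beta = [beta[i] for i in order_ix]
    pi = pi[order_ix]
    orders = tuple(orders[i] for i in order_ix)

    if not conv:
        warnings.warn("EM did not converge within max_iter in any restart", RuntimeWarning)
    return TrajectoryModel(
        J=J, orders=orders, beta=[np.asarray(b) for b in beta], sigma=sigma,
        pi=np.asarray(pi), loglik=ll, n_patients=data.n, converged=conv,
        n_restarts_used=used, time_denom=data.time_denom, loglik_trace=trace,
    )


def bic(model: TrajectoryModel) -> float:
    """Schwarz criterion in the Nagin/PROC TRAJ convention (larger is better)."""
    return model.loglik - 0.5 * model.k_params * np.log(model.n_patients)


# ---------------------------------------------------------------------------
# inference on parameters
# ---------------------------------------------------------------------------

def _full_param_loglik(theta, data, orders, J):
    """Mixture loglik over (beta..., mixing logits (J-1), log sigma)."""
    n_beta = sum(d + 1 for d in orders)
    beta, pos = [], 0
    for d in orders:
        beta.append(theta[pos : pos + d + 1])
        pos += d + 1
    logits = np.concatenate([theta[n_beta : n_beta + J - 1], [0.0]])
    pi = np.exp(logits - logsumexp(logits))
    sigma = float(np.exp(theta[-1]))
    return _mixture_loglik(data, beta, orders, sigma, pi)


def _model_theta(model: TrajectoryModel) -> np.ndarray:
    logits = np.log(model.pi) - np.log(model.pi[-1])
    return np.concatenate(
        [np.concatenate(model.beta), logits[:-1], [np.log(model.sigma)]]
    )


def param_covariance(model: TrajectoryModel, panel: pd.DataFrame) -> np.ndarray:
    """Covariance of (beta, mixing logits, log sigma) from the observed
    information matrix (numerical Hessian of the mixture log-likelihood)."""
    if model._param_cov is not None:
        return model._param_cov
    data = _prepare(panel, time_denom=model.time_denom)
    theta = _model_theta(model)
    f = lambda th: _full_param_loglik(th, data, model.orders, model.J)
    p = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        for k in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ek = np.zeros(p); ek[k] = h[k]
            if i == k:
                val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                val = (
                    f(theta + ei + ek) - f(theta + ei - ek)
                    - f(theta - ei + ek) + f(theta - ei - ek)
                ) / (4 * h[i] * h[k])
            H[i, k] = H[k, i] = val
    info = -H
    # pseudo-inverse guards against near-singular information at boundary fits
    cov = np.linalg.pinv(info)
    model._param_cov = cov
    return cov


def _beta_se(model: TrajectoryModel, panel: pd.DataFrame) -> list[np.ndarray]:
    cov = param_covariance(model, panel)
    ses, pos = [], 0
    for d in model.orders:
        block = cov[pos : pos + d + 1, pos : pos + d + 1]
        ses.append(np.sqrt(np.maximum(np.diag(block), 0.0)))
        pos += d + 1
    return ses


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_model(
    panel: pd.DataFrame,
    j_range=range(2, 8),
    seed: int = 0,
    min_group_share: float = 0.02,
    alpha: float = 0.05,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[TrajectoryModel, SelectionTrace]:
    """Three-step model selection.

    Step 1 fits all-quadratic models for each candidate number of groups
    and keeps the BIC-best among those whose smallest group share exceeds
    ``min_group_share``.  Step 2 prunes polynomial orders group by group:
    at each pass the least significant highest-order coefficient (Wald
    test at ``alpha``) is removed and the model refit, until every retained
    top-order term is significant.  Step 3 diagnostics are computed by
    :func:`diagnostics` on the chosen model.
    """
    trace = SelectionTrace()
    candidates = {}
    for J in j_range:
        try:
            m = fit_gbtm(panel, J, 2, seed=seed, tol=tol, max_iter=max_iter,
                         n_restarts=n_restarts)
        except ValueError as exc:
            trace.step1.append({"J": J, "error": str(exc)})
            continue
        rec = {
            "J": J, "orders": list(m.orders), "loglik": m.loglik, "bic": bic(m),
            "min_share": float(m.pi.min()), "converged": m.converged,
        }
        trace.step1.append(rec)
        if m.converged and m.pi.min() >= min_group_share:
            candidates[J] = m
    if not candidates:
        raise RuntimeError(f"no admissible converged candidate models; trace={trace.step1}")
    J_best = max(candidates, key=lambda J: bic(candidates[J]))
    model = candidates[J_best]

    # step 2: order pruning by Wald tests on highest-order terms
    orders = list(model.orders)
    while True:
        ses = _beta_se(model, panel)
        worst_j, worst_z = None, np.inf
        for j, d in enumerate(orders):
            if d == 0:
                continue
            se = ses[j][d]
            z = abs(model.beta[j][d]) / se if se > 0 else np.inf
            if z < worst_z:
                worst_j, worst_z = j, z
        crit = norm.ppf(1 - alpha / 2)
        trace.step2.append(
            {"orders": list(orders), "loglik": model.loglik, "bic": bic(model),
             "worst_group": worst_j, "worst_z": None if worst_j is None else worst_z}
        )
        if worst_j is None or worst_z >= crit:
            break
        orders[worst_j] -= 1
        model = fit_gbtm(panel, model.J, tuple(orders), seed=seed, tol=tol,
                         max_iter=max_iter, n_restarts=n_restarts)
        orders = list(model.orders)
    trace.chosen = {"J": model.J, "orders": list(model.orders), "bic": bic(model)}
    return model, trace


# ---------------------------------------------------------------------------
# posteriors and diagnostics
# ---------------------------------------------------------------------------

def posterior_assign(model: TrajectoryModel, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-patient posterior group probabilities and modal assignment.

    Ties break to the lowest group index.  Groups are reported 1-based.
    """
    data = _prepare(panel, time_denom=model.time_denom)
    L = _patient_group_ll(data, model.beta, model.orders, model.sigma)
    log_num = np.log(model.pi) + L
    W = np.exp(log_num - logsumexp(log_num, axis=1, keepdims=True))
    out = pd.DataFrame({"patient_id": data.patient_ids})
    for j in range(model.J):
        out[f"posterior_{j + 1}"] = W[:, j]
    out["assigned_group"] = W.argmax(axis=1) + 1
    out["max_posterior"] = W.max(axis=1)
    return out


def diagnostics(
    model: TrajectoryModel,
    assignments: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    appa_threshold: float = 0.70,
) -> Diagnostics:
    """APPA, OCC and assigned shares; optionally bundles spaghetti data."""
    J = model.J
    appa = np.full(J, np.nan)
    shares = np.zeros(J)
    n = len(assignments)
    for j in range(J):
        sel = assignments["assigned_group"] == j + 1
        shares[j] = sel.mean()
        if sel.any():
            appa[j] = assignments.loc[sel, "max_posterior"].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        occ = (appa / (1 - appa)) / (model.pi / (1 - model.pi))
    flagged = np.where(np.isnan(appa) | (appa < appa_threshold))[0]
    spaghetti = None
    if panel is not None:
        spaghetti = panel.merge(
            assignments[["patient_id", "assigned_group"]], on="patient_id"
        )
    return Diagnostics(appa, occ, shares, flagged, appa_threshold, spaghetti)


def predicted_trajectory(
    model: TrajectoryModel,
    group: int,
    t_grid,
    panel: pd.DataFrame | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Censored-normal mean PDC over time with a pointwise delta-method CI.

    ``group`` is 0-based.  The CI requires ``panel`` to compute the
    observed information; without it only the mean is returned.
    """
    if not 0 <= group < model.J:
        raise ValueError("invalid group index")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.max() > model.time_denom:
        warnings.warn("t_grid extends beyond the fitted range; extrapolating")
    s = t_grid / model.time_denom
    d = model.orders[group]
    X = np.column_stack([s**p for p in range(d + 1)])
    mu = X @ model.beta[group]
    mean = censored_normal_mean(mu, model.sigma)
    out = pd.DataFrame({"t": t_grid, "mean_pdc": mean})
    if panel is not None:
        cov = param_covariance(model, panel)
        pos = sum(dd + 1 for dd in model.orders[:group])
        cov_b = cov[pos : pos + d + 1, pos : pos + d + 1]
        # dE/dmu = Phi((1-mu)/sig) - Phi((0-mu)/sig)
        dEdmu = norm.cdf((1 - mu) / model.sigma) - norm.cdf((0 - mu) / model.sigma)
        g = X * dEdmu[:, None]
        var = np.einsum("ij,jk,ik->i", g, cov_b, g)
        se = np.sqrt(np.maximum(var, 0.0))
        zcrit = norm.ppf(0.5 + level / 2)
        out["ci_low"] = np.clip(mean - zcrit * se, 0, 1)
        out["ci_high"] = np.clip(mean + zcrit * se, 0, 1)
    return out
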