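"""Approximate measurement invariance across cohorts via a Bayesian
hierarchical item response model.

Cohort-specific item parameters (thresholds and log-discriminations) are
level-1 parameters distributed around overall level-2 means; cohorts carry
their own latent-trait means and variances.  The model is identified by
forcing, each sweep, (a) the mean threshold within every cohort to equal the
level-2 mean threshold — cohorts may differ in trait mean and variance and
single items may drift, but the *average* item difficulty is common — and
(b) the product of each cohort's discrimination parameters to one, which
pins the scale so cohort trait variances are estimable.

Sampling is Metropolis-within-Gibbs on a probit-link graded model: random
walk proposals for person traits and cohort-item parameters, conjugate
updates for the level-2 means, deviation variances and cohort trait
moments.  Per-item Bayes factors for the invariance hypothesis ("all cohort
deviations are zero") use the Savage–Dickey density ratio with the 0.3 / 3
classification rule: below 0.3 is clear differential item functioning
(DIF), above 3 clear invariance, anything between inconclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gamma as gamma_fn

import numpy as np
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError
from .irt_core import ResponseMatrix

# weakly informative priors (see docs/methods.md)
PRIOR_B_VAR = 4.0  # level-2 thresholds ~ N(0, 2^2)
PRIOR_LOGA_VAR = 1.0  # level-2 log-discriminations ~ N(0, 1)
PRIOR_DEV_SHAPE, PRIOR_DEV_SCALE = 1.0, 0.1  # deviation variances ~ IG(1, 0.1)
PRIOR_MU_VAR = 4.0  # cohort means ~ N(0, 2^2)
PRIOR_SIG_SHAPE, PRIOR_SIG_SCALE = 1.0, 1.0  # cohort variances ~ IG(1, 1)

BF_DIF = 0.3
BF_INVARIANT = 3.0


@dataclass
class McmcOptions:
    """Chain-length and tuning defaults; all overridable."""

    n_sweeps: int = 6000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    adapt_until: int | None = None  # defaults to burn_in

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_sweeps:
            raise ConfigurationError("burn_in must be smaller than n_sweeps")


@dataclass
class HierarchicalModel:
    """Retained posterior draws of the hierarchical invariance model."""

    item_ids: list[str]
    cohorts: list[str]
    n_categories: np.ndarray
    draws: dict[str, np.ndarray]
    rhat_cohort_means: np.ndarray
    converged: bool
    options: McmcOptions

    @property
    def n_draws(self) -> int:
        return self.draws["mu"].shape[0]


@dataclass
class DIFReportEntry:
    item_id: str
    bayes_factor: float
    classification: str


@dataclass
class CohortMoments:
    """Posterior summaries of cohort trait means and variances."""

    cohorts: list[str]
    mean: np.ndarray
    mean_se: np.ndarray
    variance: np.ndarray
    variance_se: np.ndarray
    between_cohort_variance: float


def subsample_cohorts(responses: ResponseMatrix, cap: int, seed: int = 0) -> ResponseMatrix:
    """Simple random sample of at most ``cap`` persons per cohort."""
    if cap < 1:
        raise InvalidParameterError("cap must be at least 1")
    rng = np.random.default_rng(seed)
    keep = np.zeros(responses.n_persons, dtype=bool)
    for cohort in np.unique(responses.cohort_ids):
        idx = np.flatnonzero(responses.cohort_ids == cohort)
        if idx.size <= cap:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=cap, replace=False)] = True
    return responses.subset_persons(keep)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _cell_loglik(theta, a, bpad, y, obs):
    """Sum over items of log P(y | theta) for a probit graded model.

    ``a``: (n, J) discriminations; ``bpad``: (n, J, K+1) thresholds padded
    with -inf / +inf; ``y``: (n, J) codes with -1 missing.
    """
    yc = np.clip(y, 0, bpad.shape[2] - 2)
    lower = np.take_along_axis(bpad, yc[:, :, None], axis=2)[:, :, 0]
    upper = np.take_along_axis(bpad, yc[:, :, None] + 1, axis=2)[:, :, 0]
    t = theta[:, None]
    p = ndtr(a * (t - lower)) - ndtr(a * (t - upper))
    logp = np.log(np.maximum(p, 1e-300))
    return np.where(obs, logp, 0.0).sum(axis=1)


def _item_loglik(theta, a, bpad_row, y, obs):
    """Log-likelihood contribution of one item for one cohort's persons."""
    yc = np.clip(y, 0, bpad_row.size - 2)
    p = ndtr(a * (theta - bpad_row[yc])) - ndtr(a * (theta - bpad_row[yc + 1]))
    return float(np.log(np.maximum(p[obs], 1e-300)).sum())


def _pad(b):
    """Pad (C, J, K-1) thresholds to (C, J, K+1) with sentinel infinities."""
    c, j, _ = b.shape
    neg = np.full((c, j, 1), -np.inf)
    pos = np.full((c, j, 1), np.inf)
    return np.concatenate([neg, b, pos], axis=2)


def _split_rhat(x: np.ndarray) -> float:
    """Split-R̂ of a single chain (split into halves)."""
    n = x.size // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def fit_hierarchical(
    responses: ResponseMatrix, options: McmcOptions | None = None
) -> HierarchicalModel:
    """MCMC fit of the hierarchical measurement-invariance model.

    Requires at least two cohorts and every item observed in every cohort.
    Returns retained draws after burn-in; flags (with a warning, not an
    error) when the split-R̂ of any cohort trait mean exceeds 1.1.
    """
    opt = options or McmcOptions()
    rng = np.random.default_rng(opt.seed)
    cohorts = sorted(np.unique(responses.cohort_ids).tolist())
    if len(cohorts) < 2:
        raise ConfigurationError("need at least two cohorts")
    y = responses.values
    cidx = np.searchsorted(np.array(cohorts), responses.cohort_ids)
    n, J = y.shape
    obs = y >= 0
    for ci, cohort in enumerate(cohorts):
        present = obs[cidx == ci]
        missing_items = [responses.item_ids[j] for j in range(J) if not present[:, j].any()]
        if missing_items:
            raise ConfigurationError(f"items {missing_items} unobserved in cohort {cohort!r}")

    n_cat = np.array([int(y[obs[:, j], j].max()) + 1 for j in range(J)])
    if np.any(n_cat < 2):
        raise ConfigurationError("every item needs at least two observed categories")
    kmax = int(n_cat.max())
    C = len(cohorts)

    # ---- initial values ----------------------------------------------------
    B = np.zeros((J, kmax - 1))
    for j in range(J):
        yo = y[obs[:, j], j]
        props = np.bincount(yo, minlength=n_cat[j]) / yo.size
        cum = np.clip(np.cumsum(props)[:-1], 0.02, 0.98)
        from scipy.stats import norm as _norm

        th = np.maximum.accumulate(_norm.ppf(cum) + 1e-6 * np.arange(n_cat[j] - 1))
        B[j, : n_cat[j] - 1] = th
        if n_cat[j] - 1 < kmax - 1:  # pad unused slots, masked out below
            B[j, n_cat[j] - 1 :] = th[-1] + 1.0 + np.arange(kmax - n_cat[j])
    th_mask = np.arange(kmax - 1)[None, :] < (n_cat - 1)[:, None]  # (J, K-1) real slots

    logA = np.zeros(J)
    b = np.tile(B, (C, 1, 1))
    loga = np.tile(logA, (C, 1))
    theta = rng.standard_normal(n) * 0.5
    mu = np.zeros(C)
    sig2 = np.ones(C)
    s2_b, s2_a = 0.1, 0.05

    step_theta = 1.0
    step_b = np.full((C, J), 0.12)
    step_a = np.full((C, J), 0.12)
    adapt_until = opt.adapt_until if opt.adapt_until is not None else opt.burn_in

    n_keep = (opt.n_sweeps - opt.burn_in) // opt.thin
    store = {
        "mu": np.empty((n_keep, C)),
        "sigma2": np.empty((n_keep, C)),
        "b": np.empty((n_keep, C, J, kmax - 1)),
        "loga": np.empty((n_keep, C, J)),
        "B": np.empty((n_keep, J, kmax - 1)),
        "logA": np.empty((n_keep, J)),
        "sigma2_b": np.empty(n_keep),
        "sigma2_a": np.empty(n_keep),
    }
    acc_theta = acc_b = acc_a = 0
    prop_b = prop_a = 1e-9
    kept = 0

    rows_by_cohort = [np.flatnonzero(cidx == ci) for ci in range(C)]

    for sweep in range(opt.n_sweeps):
        a_person = np.exp(loga)[cidx]  # (n, J)
        bpad_all = _pad(b)
        bpad_person = bpad_all[cidx]  # (n, J, K+1)

        # -- person traits (vectorized random-walk MH) ----------------------
        ll_cur = _cell_loglik(theta, a_person, bpad_person, y, obs)
        prop = theta + step_theta * rng.standard_normal(n)
        ll_prop = _cell_loglik(prop, a_person, bpad_person, y, obs)
        pri_cur = -0.5 * (theta - mu[cidx]) ** 2 / sig2[cidx]
        pri_prop = -0.5 * (prop - mu[cidx]) ** 2 / sig2[cidx]
        accept = np.log(rng.random(n)) < (ll_prop + pri_prop - ll_cur - pri_cur)
        theta = np.where(accept, prop, theta)
        acc_theta += int(accept.sum())

        # -- cohort-item parameters (blocked random-walk MH) ----------------
        for ci in range(C):
            rows = rows_by_cohort[ci]
            th_c = theta[rows]
            for j in range(J):
                k1 = n_cat[j] - 1
                o = obs[rows, j]
                yj = y[rows, j]
                bp_cur = np.concatenate([[-np.inf], b[ci, j, :k1], [np.inf]])
                ll0 = _item_loglik(th_c, np.exp(loga[ci, j]), bp_cur, yj, o)

                # thresholds
                prop_th = b[ci, j, :k1] + step_b[ci, j] * rng.standard_normal(k1)
                prop_b += 1
                if np.all(np.diff(prop_th) > 0) or k1 == 1:
                    bp_new = np.concatenate([[-np.inf], prop_th, [np.inf]])
                    ll1 = _item_loglik(th_c, np.exp(loga[ci, j]), bp_new, yj, o)
                    d_pri = -0.5 * np.sum((prop_th - B[j, :k1]) ** 2 - (b[ci, j, :k1] - B[j, :k1]) ** 2) / s2_b
                    if np.log(rng.random()) < ll1 - ll0 + d_pri:
                        b[ci, j, :k1] = prop_th
                        ll0 = ll1
                        acc_b += 1
                        bp_cur = bp_new

                # log-discrimination
                prop_la = loga[ci, j] + step_a[ci, j] * rng.standard_normal()
                prop_a += 1
                ll1 = _item_loglik(th_c, np.exp(prop_la), bp_cur, yj, o)
                d_pri = -0.5 * ((prop_la - logA[j]) ** 2 - (loga[ci, j] - logA[j]) ** 2) / s2_a
                if np.log(rng.random()) < ll1 - ll0 + d_pri:
                    loga[ci, j] = prop_la
                    acc_a += 1

        # -- level-2 means (conjugate) --------------------------------------
        for j in range(J):
            k1 = n_cat[j] - 1
            prec = C / s2_b + 1.0 / PRIOR_B_VAR
            mean = (b[:, j, :k1].sum(axis=0) / s2_b) / prec
            B[j, :k1] = mean + rng.standard_normal(k1) / np.sqrt(prec)
        prec = C / s2_a + 1.0 / PRIOR_LOGA_VAR
        logA = (loga.sum(axis=0) / s2_a) / prec + rng.standard_normal(J) / np.sqrt(prec)

        # -- deviation variances (conjugate IG) -----------------------------
        dev_b = (b - B[None, :, :]) * th_mask[None, :, :]
        n_dev_b = C * int(th_mask.sum())
        s2_b = 1.0 / rng.gamma(PRIOR_DEV_SHAPE + 0.5 * n_dev_b,
                               1.0 / (PRIOR_DEV_SCALE + 0.5 * float((dev_b**2).sum())))
        dev_a = loga - logA[None, :]
        s2_a = 1.0 / rng.gamma(PRIOR_DEV_SHAPE + 0.5 * C * J,
                               1.0 / (PRIOR_DEV_SCALE + 0.5 * float((dev_a**2).sum())))

        # -- cohort trait moments (conjugate) -------------------------------
        for ci in range(C):
            th_c = theta[rows_by_cohort[ci]]
            m = th_c.size
            prec = m / sig2[ci] + 1.0 / PRIOR_MU_VAR
            mu[ci] = (th_c.sum() / sig2[ci]) / prec + rng.standard_normal() / np.sqrt(prec)
            ssq = float(((th_c - mu[ci]) ** 2).sum())
            sig2[ci] = 1.0 / rng.gamma(PRIOR_SIG_SHAPE + 0.5 * m, 1.0 / (PRIOR_SIG_SCALE + 0.5 * ssq))

        # -- identification constraints (scale, then location) --------------
        gmean_log = loga.mean(axis=1)  # product of a = 1  <=>  mean log a = 0
        g = np.exp(gmean_log)
        loga -= gmean_log[:, None]
        for ci in range(C):
            theta[rows_by_cohort[ci]] *= g[ci]
            b[ci] *= g[ci]
        mu *= g
        sig2 *= g**2
        # anchor the trait location: overall mean item difficulty is zero
        anchor = B[th_mask].mean()
        B[th_mask] -= anchor
        b[:, th_mask] -= anchor
        theta -= anchor
        mu -= anchor
        level2_mean = 0.0
        for ci in range(C):
            delta = b[ci][th_mask].mean() - level2_mean
            b[ci][th_mask] -= delta
            theta[rows_by_cohort[ci]] -= delta
            mu[ci] -= delta

        # -- step-size adaptation during burn-in ----------------------------
        if sweep < adapt_until and (sweep + 1) % 50 == 0:
            rate = acc_theta / (50 * n)
            step_theta *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            rate_b = acc_b / max(prop_b, 1)
            step_b *= np.exp(np.clip(rate_b - 0.3, -0.5, 0.5))
            rate_a = acc_a / max(prop_a, 1)
            step_a *= np.exp(np.clip(rate_a - 0.35, -0.5, 0.5))
            acc_theta = acc_b = acc_a = 0
            prop_b = prop_a = 1e-9

        # -- storage ---------------------------------------------------------
        if sweep >= opt.burn_in and (sweep - opt.burn_in) % opt.thin == 0 and kept < n_keep:
            store["mu"][kept] = mu
            store["sigma2"][kept] = sig2
            store["b"][kept] = b
            store["loga"][kept] = loga
            store["B"][kept] = B
            store["logA"][kept] = logA
            store["sigma2_b"][kept] = s2_b
            store["sigma2_a"][kept] = s2_a
            kept += 1

    rhat = np.array([_split_rhat(store["mu"][:kept, ci]) for ci in range(C)])
    converged = bool(np.all(rhat < 1.1))
    if not converged:
        warnings.warn(
            f"cohort-mean chains may not have mixed (split-Rhat: {np.round(rhat, 3)})",
            stacklevel=2,
        )
    return HierarchicalModel(
        item_ids=list(responses.item_ids),
        cohorts=cohorts,
        n_categories=n_cat,
        draws={k: v[:kept] for k, v in store.items()},
        rhat_cohort_means=rhat,
        converged=converged,
        options=opt,
    )


# ---------------------------------------------------------------------------
# DIF Bayes factors and cohort moments
# ---------------------------------------------------------------------------


def _prior_density_at_zero() -> float:
    """Marginal prior density at 0 of one deviation, integrating the
    inverse-gamma deviation-variance prior: E[(2 pi s2)^-1/2]."""
    a, scale = PRIOR_DEV_SHAPE, PRIOR_DEV_SCALE
    return gamma_fn(a + 0.5) / gamma_fn(a) / np.sqrt(2.0 * np.pi * scale)


def classify_bayes_factor(bf: float) -> str:
    """The 0.3 / 3 decision rule for the invariance hypothesis."""
    if bf < BF_DIF:
        return "DIF"
    if bf > BF_INVARIANT:
        return "invariant"
    return "inconclusive"


def bayes_factor_dif(model: HierarchicalModel, item_id: str) -> DIFReportEntry:
    """Savage–Dickey Bayes factor for "no cohort deviation" on one item.

    For every cohort-level deviation of the item (each threshold and the
    log-discrimination), the posterior density at zero is estimated by a
    Gaussian kernel on the retained draws and divided by the marginal prior
    density at zero; the per-parameter ratios are multiplied over the item's
    parameters and cohorts.  Large values support invariance.
    """
    if item_id not in model.item_ids:
        raise KeyError(f"item {item_id!r} not in model")
    j = model.item_ids.index(item_id)
    n_draws = model.n_draws
    if n_draws < 500:
        raise InsufficientDataError(f"only {n_draws} retained draws; need >= 500 for the density ratio")
    k1 = int(model.n_categories[j]) - 1
    dev_b = model.draws["b"][:, :, j, :k1] - model.draws["B"][:, None, j, :k1]  # (S, C, k1)
    dev_a = model.draws["loga"][:, :, j] - model.draws["logA"][:, None, j]  # (S, C)
    p0 = _prior_density_at_zero()

    log_bf = 0.0
    for ci in range(len(model.cohorts)):
        for t in range(k1):
            dens = _kde_at_zero(dev_b[:, ci, t])
            log_bf += np.log(max(dens, 1e-12)) - np.log(p0)
        dens = _kde_at_zero(dev_a[:, ci])
        log_bf += np.log(max(dens, 1e-12)) - np.log(p0)
    bf = float(np.exp(np.clip(log_bf, -700, 700)))
    return DIFReportEntry(item_id, bf, classify_bayes_factor(bf))


def _kde_at_zero(draws: np.ndarray) -> float:
    sd = draws.std()
    if sd < 1e-12:  # degenerate posterior: treat as a point mass at its mean
        return 1e12 if abs(draws.mean()) < 1e-8 else 0.0
    return float(gaussian_kde(draws)(0.0)[0])


def dif_report(model: HierarchicalModel) -> list[DIFReportEntry]:
    """Bayes factor and classification for every item in the model."""
    return [bayes_factor_dif(model, iid) for iid in model.item_ids]


def cohort_moments(model: HierarchicalModel) -> CohortMoments:
    """Posterior summaries of cohort trait means/variances.

    The between-cohort variance is the posterior mean of the per-draw
    population variance of the cohort means (the "between cohort variance"
    row of a cohort-moments table).
    """
    mu = model.draws["mu"]
    sig2 = model.draws["sigma2"]
    between = float(mu.var(axis=1, ddof=0).mean())
    return CohortMoments(
        cohorts=list(model.cohorts),
        mean=mu.mean(axis=0),
        mean_se=mu.std(axis=0, ddof=1),
        variance=sig2.mean(axis=0),
        variance_se=sig2.std(axis=0, ddof=1),
        between_cohort_variance=between,
    )


def posterior_predictive_frequencies(
    model: HierarchicalModel, responses: ResponseMatrix, n_theta: int = 61
) -> dict[str, dict[str, np.ndarray]]:
    """Observed vs posterior-predictive category frequencies per cohort/item.

    Expected frequencies integrate the probit graded model at the posterior
    mean parameters over the cohort's trait distribution.
    """
    from .irt_core import quadrature

    nodes, w = quadrature(n_theta)
    out: dict[str, dict[str, np.ndarray]] = {}
    b_hat = model.draws["b"].mean(axis=0)
    a_hat = np.exp(model.draws["loga"]).mean(axis=0)
    mu_hat = model.draws["mu"].mean(axis=0)
    sd_hat = np.sqrt(model.draws["sigma2"].mean(axis=0))
    cidx = np.searchsorted(np.array(model.cohorts), responses.cohort_ids)
    for ci, cohort in enumerate(model.cohorts):
        grid = mu_hat[ci] + sd_hat[ci] * nodes
        rows = np.flatnonzero(cidx == ci)
        per_item = {}
        for j, iid in enumerate(model.item_ids):
            k = int(model.n_categories[j])
            bp = np.concatenate([[-np.inf], b_hat[ci, j, : k - 1], [np.inf]])
            cum = ndtr(a_hat[ci, j] * (grid[:, None] - bp[None, :]))
            probs = cum[:, :-1] - cum[:, 1:]
            expected = w @ probs
            yj = responses.values[rows, j]
            yo = yj[yj >= 0]
            observed = np.bincount(yo, minlength=k) / max(yo.size, 1)
            per_item[iid] = np.vstack([observed[:k], expected])
        out[cohort] = per_item
    return out
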