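"""Graded-response IRT engine.

Implements the logistic graded response model (GRM) for ordinal items —
dichotomous items are the two-category special case (2PL) — together with
Fisher information curves, marginal maximum-likelihood (MML) calibration via
the EM algorithm with fixed-node quadrature, and EAP scoring under arbitrary
missingness.

The latent trait is identified by fixing its prior to the standard normal
during single-sample calibration; linking across inventories and cohorts is
handled in :mod:`traitlink.linking` and :mod:`traitlink.invariance`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import DegenerateItemError, InvalidParameterError

logger = logging.getLogger(__name__)

MISSING = -1  # integer code for a missing response


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemParameters:
    """Discrimination and ordered thresholds of one graded-response item.

    The discrimination ``a`` plays the role of a factor loading: the larger
    it is, the more strongly the response depends on the latent trait.  The
    K-1 thresholds ``b`` locate the points on the trait scale where adjacent
    cumulative response probabilities cross one half, analogous to liability
    thresholds.
    """

    discrimination: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        th = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        object.__setattr__(self, "thresholds", th)
        if th.size < 1:
            raise InvalidParameterError("need at least one threshold (K >= 2)")
        if np.any(np.diff(th) <= 0):
            raise InvalidParameterError(f"thresholds must be strictly increasing, got {th}")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with missingness and cohort labels.

    ``values`` holds integer codes in ``{0..K-1}`` with ``MISSING`` (-1) for
    unobserved cells.
    """

    values: np.ndarray
    person_ids: np.ndarray
    item_ids: list[str]
    cohort_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.person_ids = np.asarray(self.person_ids)
        self.cohort_ids = np.asarray(self.cohort_ids)
        self.item_ids = list(self.item_ids)
        n, j = self.values.shape
        if len(self.person_ids) != n or len(self.cohort_ids) != n:
            raise InvalidParameterError("person/cohort id length mismatch")
        if len(self.item_ids) != j:
            raise InvalidParameterError("item id length mismatch")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def subset_items(self, item_ids: list[str]) -> "ResponseMatrix":
        cols = [self.column(i) for i in item_ids]
        return ResponseMatrix(self.values[:, cols], self.person_ids, list(item_ids), self.cohort_ids)

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            self.values[mask], self.person_ids[mask], list(self.item_ids), self.cohort_ids[mask]
        )


@dataclass
class Calibration:
    """Item-parameter estimates obtained on a particular sample and item set."""

    items: dict[str, ItemParameters]
    n_used: int = 0
    cohort: str | None = None
    log_likelihood: float = float("nan")
    converged: bool = True
    n_iterations: int = 0
    category_maps: dict[str, np.ndarray] = field(default_factory=dict)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def item_ids(self) -> list[str]:
        return list(self.items)


@dataclass
class LatentScores:
    """Posterior mean and SD of the latent trait per person (EAP)."""

    person_ids: np.ndarray
    cohort_ids: np.ndarray
    score: np.ndarray
    sd: np.ndarray
    n_items: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise InvalidParameterError("posterior SDs must be positive")


@dataclass
class InformationCurve:
    """Test information (Fisher information summed over items) on a trait grid."""

    grid: np.ndarray
    information: np.ndarray

    def __add__(self, other: "InformationCurve") -> "InformationCurve":
        if not np.array_equal(self.grid, other.grid):
            raise InvalidParameterError("information curves on different grids")
        return InformationCurve(self.grid, self.information + other.information)


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------


def quadrature(n_nodes: int = 61, bound: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed equally-spaced nodes on [-bound, bound] with standard-normal weights."""
    nodes = np.linspace(-bound, bound, n_nodes)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def grm_category_prob(theta, params: ItemParameters) -> np.ndarray:
    """Category probabilities of the graded response model.

    ``P(Y >= k | theta) = logistic(a (theta - b_k))`` for k = 1..K-1, and the
    category probabilities are successive differences of these cumulative
    curves.  Returns an array with trailing dimension K; a scalar ``theta``
    yields a length-K vector.
    """
    theta = np.asarray(theta, dtype=float)
    a = params.discrimination
    star = expit(a * (theta[..., None] - params.thresholds))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    upper = np.concatenate([ones, star], axis=-1)
    lower = np.concatenate([star, zeros], axis=-1)
    return upper - lower


def item_information(theta, params: ItemParameters) -> np.ndarray:
    """Fisher information of one graded item at trait value(s) ``theta``.

    Computed as sum over categories of (dP/dtheta)^2 / P.
    """
    theta = np.asarray(theta, dtype=float)
    a = params.discrimination
    star = expit(a * (theta[..., None] - params.thresholds))
    dstar = a * star * (1.0 - star)
    zeros = np.zeros(theta.shape + (1,))
    dupper = np.concatenate([zeros, dstar], axis=-1)
    dlower = np.concatenate([dstar, zeros], axis=-1)
    dprob = dupper - dlower
    prob = grm_category_prob(theta, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(prob > 1e-12, dprob**2 / np.maximum(prob, 1e-12), 0.0)
    return terms.sum(axis=-1)


def test_information(
    calib: Calibration, item_ids: list[str] | None = None, grid: np.ndarray | None = None
) -> InformationCurve:
    """Pointwise sum of item informations over a subset of calibrated items."""
    if grid is None:
        grid = np.linspace(-4, 4, 81)
    grid = np.asarray(grid, dtype=float)
    if item_ids is None:
        item_ids = calib.item_ids
    info = np.zeros_like(grid)
    for iid in item_ids:
        if iid not in calib.items:
            raise KeyError(f"item {iid!r} not in calibration")
        info += item_information(grid, calib.items[iid])
    return InformationCurve(grid, info)


# ---------------------------------------------------------------------------
# MML calibration (Bock–Aitkin EM)
# ---------------------------------------------------------------------------


@dataclass
class CalibrationOptions:
    """Tuning knobs for :func:`calibrate_mml`.

    ``tol`` is the maximum absolute parameter change that stops EM;
    ``complete_cases`` restricts the fitting sample to persons with no
    missing response on the fitted items (the convention for single-inventory
    calibrations); categories observed fewer than ``collapse_threshold``
    times are merged into the adjacent category to avoid degenerate
    thresholds.
    """

    tol: float = 1e-4
    max_iter: int = 500
    n_nodes: int = 61
    complete_cases: bool = False
    collapse_threshold: int = 5


def _collapse_sparse(y: np.ndarray, threshold: int, item_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Merge categories observed < threshold times into the adjacent category.

    Returns the recoded column and the code map (original -> new).  Missing
    entries (-1) pass through untouched.
    """
    obs = y[y >= 0]
    if obs.size == 0:
        raise DegenerateItemError(f"item {item_id!r} has no observed responses")
    kmax = int(obs.max()) + 1
    counts = np.bincount(obs, minlength=kmax)
    keep = counts >= threshold
    # never drop everything: retain the two best-filled categories at minimum
    if keep.sum() < 2:
        order = np.argsort(counts)[::-1]
        keep[:] = False
        keep[order[:2]] = True
    codemap = np.zeros(kmax, dtype=np.int64)
    new = -1
    for k in range(kmax):
        if keep[k]:
            new += 1
        codemap[k] = max(new, 0)
    if codemap.max() < 1:
        raise DegenerateItemError(f"item {item_id!r} has a single observed category")
    if not np.all(keep[counts > 0]):
        logger.warning("item %s: sparse categories collapsed (counts %s)", item_id, counts.tolist())
    out = y.copy()
    out[y >= 0] = codemap[obs]
    return out, codemap


def _start_values(y: np.ndarray, n_cat: int) -> ItemParameters:
    """Classic start: a = 1, thresholds from inverse-normal cumulative proportions."""
    obs = y[y >= 0]
    props = np.bincount(obs, minlength=n_cat) / obs.size
    cum = np.cumsum(props)[:-1]
    cum = np.clip(cum, 0.02, 0.98)
    th = norm.ppf(cum)
    th = np.maximum.accumulate(th + 1e-6 * np.arange(th.size))
    return ItemParameters(1.0, th)


def _pack(p: ItemParameters) -> np.ndarray:
    th = p.thresholds
    x = np.empty(1 + th.size)
    x[0] = np.log(p.discrimination)
    x[1] = th[0]
    if th.size > 1:
        x[2:] = np.log(np.diff(th))
    return x


def _unpack(x: np.ndarray) -> ItemParameters:
    a = float(np.exp(np.clip(x[0], -4.0, 4.0)))
    incr = np.exp(np.clip(x[2:], -8.0, 4.0))
    th = x[1] + np.concatenate([[0.0], np.cumsum(incr)])
    return ItemParameters(a, th)


def _expected_neg_loglik(x: np.ndarray, nodes: np.ndarray, r: np.ndarray) -> float:
    """Negative expected complete-data log-likelihood for one item.

    ``r`` is the (n_nodes x K) matrix of expected response counts from the
    E-step.
    """
    params = _unpack(x)
    prob = grm_category_prob(nodes, params)
    return -float(np.sum(r * np.log(np.maximum(prob, 1e-300))))


def _log_prob_tables(items: list[ItemParameters], nodes: np.ndarray) -> list[np.ndarray]:
    return [np.log(np.maximum(grm_category_prob(nodes, p), 1e-300)) for p in items]


def _person_loglik(y: np.ndarray, logp: list[np.ndarray]) -> np.ndarray:
    """(n_persons x n_nodes) log-likelihood over observed items only."""
    n, j = y.shape
    q = logp[0].shape[0]
    ll = np.zeros((n, q))
    for col in range(j):
        yj = y[:, col]
        obs = yj >= 0
        if obs.any():
            ll[obs] += logp[col][:, yj[obs]].T
    return ll


def calibrate_mml(
    responses: ResponseMatrix, options: CalibrationOptions | None = None
) -> Calibration:
    """Marginal maximum-likelihood GRM calibration via the EM algorithm.

    The latent prior is fixed to the standard normal (identification); the
    marginal likelihood is integrated on a fixed quadrature grid; the M-step
    maximizes each item's expected complete-data log-likelihood, so the
    marginal log-likelihood is monotone non-decreasing across EM cycles.
    """
    opt = options or CalibrationOptions()
    y = responses.values.copy()

    if opt.complete_cases:
        keep = np.all(y >= 0, axis=1)
        y = y[keep]
        if y.shape[0] == 0:
            raise DegenerateItemError("no complete cases in the fitting sample")
    else:
        keep_any = np.any(y >= 0, axis=1)
        y = y[keep_any]

    n, j = y.shape
    category_maps: dict[str, np.ndarray] = {}
    n_cats = []
    for col, iid in enumerate(responses.item_ids):
        y[:, col], codemap = _collapse_sparse(y[:, col], opt.collapse_threshold, iid)
        category_maps[iid] = codemap
        obs = y[:, col][y[:, col] >= 0]
        ncat = int(obs.max()) + 1
        if np.unique(obs).size < 2:
            raise DegenerateItemError(f"item {iid!r} has a single observed category")
        n_cats.append(ncat)

    nodes, weights = quadrature(opt.n_nodes)
    logw = np.log(weights)
    params = [_start_values(y[:, col], n_cats[col]) for col in range(j)]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opt.max_iter + 1):
        logp = _log_prob_tables(params, nodes)
        ll = _person_loglik(y, logp) + logw
        marg = logsumexp(ll, axis=1)
        trace.append(float(marg.sum()))
        post = np.exp(ll - marg[:, None])  # (n, q)

        max_change = 0.0
        new_params = []
        for col in range(j):
            yj = y[:, col]
            obs = yj >= 0
            k = n_cats[col]
            r = np.zeros((nodes.size, k))
            pobs = post[obs]
            yobs = yj[obs]
            for c in range(k):
                sel = yobs == c
                if sel.any():
                    r[:, c] = pobs[sel].sum(axis=0)
            x0 = _pack(params[col])
            res = minimize(
                _expected_neg_loglik,
                x0,
                args=(nodes, r),
                method="L-BFGS-B",
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
            )
            cand = res.x if res.fun <= _expected_neg_loglik(x0, nodes, r) else x0
            p_new = _unpack(cand)
            old = params[col]
            max_change = max(
                max_change,
                abs(p_new.discrimination - old.discrimination),
                float(np.max(np.abs(p_new.thresholds - old.thresholds))),
            )
            new_params.append(p_new)
        params = new_params
        if max_change < opt.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"MML calibration did not converge in {opt.max_iter} EM cycles "
            f"(last max parameter change above tolerance)",
            stacklevel=2,
        )

    # final marginal log-likelihood at the returned parameters
    logp = _log_prob_tables(params, nodes)
    ll = _person_loglik(y, logp) + logw
    loglik = float(logsumexp(ll, axis=1).sum())

    return Calibration(
        items=dict(zip(responses.item_ids, params)),
        n_used=n,
        log_likelihood=loglik,
        converged=converged,
        n_iterations=it,
        category_maps=category_maps,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------


def score_eap(
    responses: ResponseMatrix, calib: Calibration, n_nodes: int = 61
) -> LatentScores:
    """Expected-a-posteriori latent scores under a calibration.

    Each person's posterior over the standard-normal prior uses only that
    person's observed items (missing items are skipped — missing-at-random).
    Persons with zero observed items receive the prior mean 0 and SD 1 and
    are flagged by ``n_items == 0``.
    """
    for iid in responses.item_ids:
        if iid not in calib.items:
            raise KeyError(f"item {iid!r} not covered by the calibration")
    y = responses.values.copy()
    # apply the calibration's sparse-category collapsing so codes match
    for col, iid in enumerate(responses.item_ids):
        codemap = calib.category_maps.get(iid)
        if codemap is not None:
            obs = y[:, col] >= 0
            codes = np.clip(y[:, col][obs], 0, codemap.size - 1)
            y[obs, col] = codemap[codes]

    nodes, weights = quadrature(n_nodes)
    logw = np.log(weights)
    items = [calib.items[iid] for iid in responses.item_ids]
    logp = _log_prob_tables(items, nodes)
    ll = _person_loglik(y, logp) + logw
    post = np.exp(ll - logsumexp(ll, axis=1)[:, None])
    mean = post @ nodes
    var = post @ nodes**2 - mean**2
    sd = np.sqrt(np.maximum(var, 1e-12))
    n_items = (y >= 0).sum(axis=1)
    none = n_items == 0
    mean[none] = 0.0
    sd[none] = 1.0
    return LatentScores(responses.person_ids, responses.cohort_ids, mean, sd, n_items)
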