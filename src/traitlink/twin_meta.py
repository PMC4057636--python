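"""Twin correlations and ADE meta-analysis with sex-limitation tests.

Two layers:

* :func:`fit_saturated_twin` estimates sex-by-zygosity twin correlations
  from raw pair scores by maximum likelihood under a saturated bivariate
  normal model — one mean, one variance and one covariance per group plus a
  single age slope on the means — using the marginal likelihood for pairs
  where only one twin was scored.
* :func:`fit_ade_meta` pools correlations from several cohorts under the
  classical ADE twin model, with additive (h^2) and dominance (d^2) variance
  proportions optionally sex-specific and the opposite-sex (DOS) correlation
  optionally free, and :func:`lrt_sequence` runs the nested test sequence
  for qualitative sex effects, quantitative sex effects and dominance.

Model-expected correlations: r(MZ) = h^2 + d^2, r(same-sex DZ) =
h^2/2 + d^2/4, r(DOS) = h_m h_f / 2 + d_m d_f / 4 unless freed.

The pooled discrepancy is, by default, the normal-theory ML fit function for
a 2x2 correlation matrix summed over groups with weight N (the printed pair
count); a Fisher-z weighted least squares alternative (weights N-3) is
available via ``discrepancy="fisher-z"``.  Both are asymptotically chi-square
with df = number of correlations minus free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .errors import ConfigurationError, InvalidParameterError

GROUPS = ("MZM", "DZM", "MZF", "DZF", "DOS")

MODEL_LABELS = ("base", "no-qualitative", "no-quantitative", "no-dominance")


# ---------------------------------------------------------------------------
# saturated per-cohort model
# ---------------------------------------------------------------------------


@dataclass
class GroupEstimate:
    mean: float
    variance: float
    covariance: float
    correlation: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_complete: int


@dataclass
class SaturatedTwinFit:
    """Per-group moments and correlations from the saturated twin model."""

    cohort: str
    groups: dict[str, GroupEstimate]
    age_slope: float
    log_likelihood: float
    n_parameters: int


def _group_loglik(s1, s2, age, mu, var, cov, beta):
    m = mu + beta * age
    both = ~np.isnan(s1) & ~np.isnan(s2)
    one1 = ~np.isnan(s1) & np.isnan(s2)
    one2 = np.isnan(s1) & ~np.isnan(s2)
    ll = 0.0
    det = var * var - cov * cov
    if det <= 0 or var <= 0:
        return -np.inf
    if both.any():
        d1 = s1[both] - m[both]
        d2 = s2[both] - m[both]
        quad = (var * d1**2 - 2 * cov * d1 * d2 + var * d2**2) / det
        ll += float(-0.5 * np.sum(quad) - both.sum() * (np.log(2 * np.pi) + 0.5 * np.log(det)))
    for mask, s in ((one1, s1), (one2, s2)):
        if mask.any():
            d = s[mask] - m[mask]
            ll += float(
                -0.5 * np.sum(d**2) / var - mask.sum() * 0.5 * (np.log(2 * np.pi) + np.log(var))
            )
    return ll


def fit_saturated_twin(
    data: pd.DataFrame, cohort: str | None = None, fit_age: bool = True
) -> SaturatedTwinFit:
    """Saturated ML fit: one mean/variance/covariance per sex-by-zygosity
    group, one shared age slope, incomplete pairs via their marginal
    likelihood.

    With a DOS group present the model has 16 parameters (5 means, 1 age
    slope, 5 variances, 5 covariances); without, 13.
    """
    df = data if cohort is None else data[data["cohort"] == cohort]
    if df.empty:
        raise InvalidParameterError("no rows for requested cohort")
    groups = [g for g in GROUPS if g in set(df["group"])]
    if not groups:
        raise ConfigurationError("no recognised twin groups in data")

    arrays = {}
    for g in groups:
        sub = df[df["group"] == g]
        arrays[g] = (
            sub["score1"].to_numpy(float),
            sub["score2"].to_numpy(float),
            sub["age"].to_numpy(float),
        )

    # start values from pairwise moments
    x0 = []
    for g in groups:
        s1, s2, _ = arrays[g]
        allscores = np.concatenate([s1[~np.isnan(s1)], s2[~np.isnan(s2)]])
        v = max(np.var(allscores), 1e-3)
        both = ~np.isnan(s1) & ~np.isnan(s2)
        c = np.cov(s1[both], s2[both])[0, 1] if both.sum() >= 2 else 0.0
        r0 = np.clip(c / v, -0.95, 0.95)
        x0 += [float(np.mean(allscores)), float(np.log(v)), float(np.arctanh(r0))]
    x0.append(0.0)  # age slope

    def unpack(x):
        out = {}
        for i, g in enumerate(groups):
            mu, logv, z = x[3 * i : 3 * i + 3]
            v = np.exp(logv)
            out[g] = (mu, v, np.tanh(z) * v)
        beta = x[-1] if fit_age else 0.0
        return out, beta

    def negll(x):
        pars, beta = unpack(x)
        total = 0.0
        for g in groups:
            s1, s2, age = arrays[g]
            mu, v, c = pars[g]
            total += _group_loglik(s1, s2, age, mu, v, c, beta)
        return -total

    nfree = 3 * len(groups) + (1 if fit_age else 0)
    res = minimize(negll, np.array(x0), method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
    pars, beta = unpack(res.x)

    out_groups = {}
    for g in groups:
        s1, s2, _ = arrays[g]
        both = ~np.isnan(s1) & ~np.isnan(s2)
        n_complete = int(both.sum())
        mu, v, c = pars[g]
        r = c / v
        if n_complete == 0:
            r, lo, hi = float("nan"), float("nan"), float("nan")
        elif n_complete > 3:
            z = np.arctanh(np.clip(r, -0.999999, 0.999999))
            se = 1.0 / np.sqrt(n_complete - 3)
            lo, hi = float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se))
        else:
            lo, hi = -1.0, 1.0
        out_groups[g] = GroupEstimate(
            mean=float(mu),
            variance=float(v),
            covariance=float(c),
            correlation=float(r),
            ci_low=lo,
            ci_high=hi,
            n_pairs=len(s1),
            n_complete=n_complete,
        )
    # parameter count reported for the full saturated model (age always counted)
    n_params = 3 * len(groups) + 1
    return SaturatedTwinFit(
        cohort=cohort or "all",
        groups=out_groups,
        age_slope=float(beta),
        log_likelihood=float(-res.fun),
        n_parameters=n_params,
    )


def correlation_table(fits: list[SaturatedTwinFit], trait: str = "trait") -> pd.DataFrame:
    """Assemble per-cohort saturated fits into the pooled correlation table."""
    rows = []
    for fit in fits:
        for g, est in fit.groups.items():
            if np.isnan(est.correlation):
                continue
            rows.append(
                {"cohort": fit.cohort, "group": g, "trait": trait, "r": est.correlation, "n": est.n_pairs}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ADE expectations
# ---------------------------------------------------------------------------


@dataclass
class ADEParameters:
    """Sex-specific ADE variance proportions plus derived expectations.

    Stored as path coefficients (``h``, ``d`` >= 0, proportions are their
    squares) so nonnegativity is built in; ``r_dos_free`` holds the freely
    estimated opposite-sex correlation when the model allows a qualitative
    sex effect, else ``None``.
    """

    h_m: float
    h_f: float
    d_m: float
    d_f: float
    r_dos_free: float | None = None
    model: str = "base"

    @property
    def h2_m(self) -> float:
        return self.h_m**2

    @property
    def h2_f(self) -> float:
        return self.h_f**2

    @property
    def d2_m(self) -> float:
        return self.d_m**2

    @property
    def d2_f(self) -> float:
        return self.d_f**2

    @property
    def e2_m(self) -> float:
        return 1.0 - self.h2_m - self.d2_m

    @property
    def e2_f(self) -> float:
        return 1.0 - self.h2_f - self.d2_f

    @property
    def dos_expectation(self) -> float:
        """Expected DOS correlation under no qualitative sex differences."""
        return 0.5 * self.h_m * self.h_f + 0.25 * self.d_m * self.d_f


def expected_twin_correlations(params: ADEParameters, group: str) -> float:
    """Model-expected twin correlation for one sex-by-zygosity group."""
    if group == "MZM":
        return params.h2_m + params.d2_m
    if group == "MZF":
        return params.h2_f + params.d2_f
    if group == "DZM":
        return 0.5 * params.h2_m + 0.25 * params.d2_m
    if group == "DZF":
        return 0.5 * params.h2_f + 0.25 * params.d2_f
    if group == "DOS":
        if params.r_dos_free is not None:
            return params.r_dos_free
        return params.dos_expectation
    raise ConfigurationError(f"unknown twin group {group!r}")


# ---------------------------------------------------------------------------
# meta-analysis of correlations
# ---------------------------------------------------------------------------


@dataclass
class MetaFit:
    """One fitted ADE meta-model: discrepancy, df and estimates."""

    model: str
    chisq: float
    df: int
    n_free: int
    params: ADEParameters
    discrepancy: str
    boundary: bool = False
    comparisons: list[dict] = field(default_factory=list)


def _ml_discrepancy(r: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Normal-theory ML fit function for a 2x2 correlation matrix."""
    return np.log((1 - rho**2) / (1 - r**2)) + 2 * (1 - r * rho) / (1 - rho**2) - 2


def _model_spec(model: str, free_dos: bool | None):
    if model not in MODEL_LABELS:
        raise ConfigurationError(f"unknown model label {model!r}; choose from {MODEL_LABELS}")
    if free_dos is None:
        free_dos = model == "base"
    sex_specific = model in ("base", "no-qualitative")
    dominance = model != "no-dominance"
    if model == "base":
        free_dos = True
    return sex_specific, dominance, free_dos


def fit_ade_meta(
    table: pd.DataFrame,
    model: str = "base",
    free_dos: bool | None = None,
    discrepancy: str = "ml",
) -> MetaFit:
    """Fit an ADE meta-model to a table of twin correlations.

    ``table`` needs columns ``group``, ``r`` and ``n`` (one row per cohort x
    group).  Model labels: ``base`` (sex-specific paths + free DOS
    correlation), ``no-qualitative`` (DOS at its expectation),
    ``no-quantitative`` (sex-equal paths), ``no-dominance`` (sex-equal,
    d = 0).  For the sex-equal models ``free_dos=True`` keeps the
    qualitative sex effect while equating the variance components.
    """
    if discrepancy not in ("ml", "fisher-z"):
        raise ConfigurationError("discrepancy must be 'ml' or 'fisher-z'")
    sex_specific, dominance, free_dos = _model_spec(model, free_dos)
    needed = {"group", "r", "n"}
    if not needed.issubset(table.columns):
        raise ConfigurationError(f"correlation table must have columns {sorted(needed)}")
    groups = table["group"].to_numpy()
    unknown = set(groups) - set(GROUPS)
    if unknown:
        raise ConfigurationError(f"unknown twin groups {sorted(unknown)}")
    has_dos = "DOS" in groups
    if free_dos and not has_dos:
        raise ConfigurationError("free DOS correlation requested but no DOS rows present")

    r = table["r"].to_numpy(float)
    n = table["n"].to_numpy(float)
    z = np.arctanh(r)
    w_fz = n - 3.0

    names = []
    if sex_specific:
        names += ["h_m", "h_f"] + (["d_m", "d_f"] if dominance else [])
    else:
        names += ["h"] + (["d"] if dominance else [])
    if free_dos:
        names += ["r_dos"]
    n_free = len(names)

    def to_params(x) -> ADEParameters:
        vals = dict(zip(names, x))
        if sex_specific:
            hm, hf = vals["h_m"], vals["h_f"]
            dm, df_ = (vals.get("d_m", 0.0), vals.get("d_f", 0.0))
        else:
            hm = hf = vals["h"]
            dm = df_ = vals.get("d", 0.0)
        return ADEParameters(
            h_m=hm, h_f=hf, d_m=dm, d_f=df_,
            r_dos_free=vals.get("r_dos"), model=model,
        )

    def objective(x):
        p = to_params(x)
        rho = np.array([expected_twin_correlations(p, g) for g in groups])
        rho = np.clip(rho, -0.999, 0.999)
        if discrepancy == "ml":
            return float(np.sum(n * _ml_discrepancy(r, rho)))
        return float(np.sum(w_fz * (z - np.arctanh(rho)) ** 2))

    bounds = [(0.0, 0.999)] * (n_free - (1 if free_dos else 0)) + (
        [(-0.99, 0.99)] if free_dos else []
    )
    starts = [0.2, 0.35, 0.5, 0.65, 0.8]
    best = None
    for s in starts:
        x0 = np.full(n_free, s)
        if free_dos:
            x0[-1] = 0.15
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    # simplex polish for high-precision minima (perfect-fit recovery)
    polish = minimize(
        objective, best.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
    )
    if polish.fun <= best.fun:
        best = polish

    params = to_params(best.x)
    path_vals = [v for k, v in zip(names, best.x) if k != "r_dos"]
    boundary = any(v < 1e-4 or v > 0.999 - 1e-4 for v in path_vals)
    return MetaFit(
        model=model,
        chisq=float(best.fun),
        df=len(r) - n_free,
        n_free=n_free,
        params=params,
        discrepancy=discrepancy,
        boundary=boundary,
    )


def lrt_sequence(table: pd.DataFrame, discrepancy: str = "ml",
                 alpha_sex: float = 0.01, alpha_other: float = 0.05) -> dict:
    """The nested model-comparison sequence on a pooled correlation table.

    Step 1 tests qualitative sex effects (free DOS correlation vs its
    expectation), step 2 quantitative sex effects (sex-specific vs equal
    variance components, carrying the qualitative decision forward), step 3
    dominance (d^2 = 0).  Sex-difference steps use ``alpha_sex``
    (p < 0.01 convention), the dominance step ``alpha_other``.
    """
    has_dos = "DOS" in set(table["group"])
    comparisons = []

    if has_dos:
        base = fit_ade_meta(table, "base", discrepancy=discrepancy)
        noqual = fit_ade_meta(table, "no-qualitative", discrepancy=discrepancy)
        dchi = noqual.chisq - base.chisq
        ddf = noqual.df - base.df
        sig = dchi > stats.chi2.isf(alpha_sex, ddf)
        comparisons.append(
            {"comparison": "qualitative sex effects", "delta_chisq": dchi, "delta_df": ddf,
             "significant": bool(sig), "alpha": alpha_sex}
        )
        keep_free_dos = bool(sig)
        accepted = base if keep_free_dos else noqual
    else:
        keep_free_dos = False
        accepted = fit_ade_meta(table, "no-qualitative", free_dos=False, discrepancy=discrepancy)

    noquant = fit_ade_meta(table, "no-quantitative", free_dos=keep_free_dos, discrepancy=discrepancy)
    dchi = noquant.chisq - accepted.chisq
    ddf = noquant.df - accepted.df
    sig = dchi > stats.chi2.isf(alpha_sex, ddf)
    comparisons.append(
        {"comparison": "quantitative sex effects", "delta_chisq": dchi, "delta_df": ddf,
         "significant": bool(sig), "alpha": alpha_sex}
    )
    accepted_quant = accepted if sig else noquant

    if accepted_quant.model == "no-quantitative":
        nodom = fit_ade_meta(table, "no-dominance", free_dos=keep_free_dos, discrepancy=discrepancy)
    else:
        # dominance dropped from the sex-specific model: refit without d paths
        nodom = fit_ade_meta(table, "no-dominance", free_dos=keep_free_dos, discrepancy=discrepancy)
    dchi = nodom.chisq - accepted_quant.chisq
    ddf = nodom.df - accepted_quant.df
    sig = dchi > stats.chi2.isf(alpha_other, ddf)
    comparisons.append(
        {"comparison": "dominance variance", "delta_chisq": dchi, "delta_df": ddf,
         "significant": bool(sig), "alpha": alpha_other}
    )
    selected = accepted_quant if sig else nodom
    selected.comparisons = comparisons
    return {"comparisons": comparisons, "selected": selected}
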