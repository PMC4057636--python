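"""Synthetic multi-cohort, multi-inventory study generator.

Produces every input the harmonization pipeline consumes: ordinal item
responses driven by a unidimensional latent trait with cohort-specific means
and variances, structured missingness where only a "bridge" subsample holds
two or more inventories, cohort-level item-parameter deviations (DIF), twin
pairs with additive + dominance genetic covariance, and a biallelic SNP
explaining a fixed fraction of latent variance.

All generators are deterministic given their seed; one integer seed can be
split into per-stage sub-streams via :func:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .irt_core import MISSING, ItemParameters, ResponseMatrix, grm_category_prob

TWIN_GROUPS = ("MZM", "DZM", "MZF", "DZF", "DOS")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InventorySpec:
    """One inventory: its name, item count, and categories per item."""

    name: str
    n_items: int
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise InvalidParameterError("inventory needs at least one item")
        if self.n_categories < 2:
            raise InvalidParameterError("items need at least two categories")


@dataclass
class SimulationConfig:
    """Study-level design for the multi-cohort item-response generator."""

    n_cohorts: int = 2
    persons_per_cohort: int = 1000
    cohort_trait_means: list[float] = field(default_factory=lambda: [0.0, 0.0])
    cohort_trait_variances: list[float] = field(default_factory=lambda: [1.0, 1.0])
    inventories: list[InventorySpec] = field(
        default_factory=lambda: [InventorySpec("A", 12, 5), InventorySpec("B", 12, 5)]
    )
    bridge_fraction: float = 0.3
    dif_sd: float = 0.0
    dif_items: tuple[str, ...] = ()
    dif_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_trait_means) != self.n_cohorts:
            raise ConfigurationError("one trait mean per cohort required")
        if len(self.cohort_trait_variances) != self.n_cohorts:
            raise ConfigurationError("one trait variance per cohort required")
        if any(v <= 0 for v in self.cohort_trait_variances):
            raise InvalidParameterError("cohort trait variances must be positive")
        if not 0.0 <= self.bridge_fraction <= 1.0:
            raise InvalidParameterError("bridge_fraction must lie in [0, 1]")
        if self.dif_sd < 0:
            raise InvalidParameterError("dif_sd must be nonnegative")


@dataclass
class TwinSimConfig:
    """Design for the ADE twin-pair generator.

    ``h2`` and ``d2`` are the proportions of trait variance due to additive
    and dominance genetic effects per sex; the cross-sex genetic sharing of
    opposite-sex (DOS) pairs is scaled by ``genetic_correlation_dos`` so a
    value below 1 generates qualitative sex differences.
    """

    pairs_per_group: dict[str, int] = field(
        default_factory=lambda: {"MZM": 1000, "DZM": 1000, "MZF": 1000, "DZF": 1000, "DOS": 1000}
    )
    h2_m: float = 0.27
    h2_f: float = 0.27
    d2_m: float = 0.21
    d2_f: float = 0.21
    genetic_correlation_dos: float = 1.0
    age_slope: float = 0.0
    age_range: tuple[float, float] = (18.0, 60.0)
    missing_cotwin_fraction: float = 0.0
    cohort: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("h2_m", self.h2_m), ("h2_f", self.h2_f), ("d2_m", self.d2_m), ("d2_f", self.d2_f)):
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.h2_m + self.d2_m > 1.0 or self.h2_f + self.d2_f > 1.0:
            raise InvalidParameterError("h2 + d2 must not exceed 1 within each sex")
        if not 0.0 <= self.genetic_correlation_dos <= 1.0:
            raise InvalidParameterError("genetic_correlation_dos must lie in [0, 1]")
        if not 0.0 <= self.missing_cotwin_fraction <= 1.0:
            raise InvalidParameterError("missing_cotwin_fraction must lie in [0, 1]")
        for g in self.pairs_per_group:
            if g not in TWIN_GROUPS:
                raise ConfigurationError(f"unknown twin group {g!r}")


@dataclass(frozen=True)
class SnpDesign:
    """A biallelic SNP explaining a fraction ``q2`` of latent-trait variance."""

    maf: float = 0.5
    q2: float = 0.001
    n: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise InvalidParameterError("maf must lie strictly inside (0, 1)")
        if not 0.0 <= self.q2 < 1.0:
            raise InvalidParameterError("q2 must lie in [0, 1)")
        if self.n < 1:
            raise InvalidParameterError("n must be positive")


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------


def gen_latent_traits(n: int, mean: float = 0.0, variance: float = 1.0, seed: int = 0) -> np.ndarray:
    """Draw ``n`` latent trait values from N(mean, variance)."""
    if n < 1:
        raise InvalidParameterError("n must be at least 1")
    if variance <= 0:
        raise InvalidParameterError("variance must be positive")
    rng = np.random.default_rng(seed)
    return mean + np.sqrt(variance) * rng.standard_normal(n)


def _probit_category_prob(theta: np.ndarray, p: ItemParameters) -> np.ndarray:
    from scipy.special import ndtr

    star = ndtr(p.discrimination * (theta[..., None] - p.thresholds))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    return np.concatenate([ones, star], axis=-1) - np.concatenate([star, zeros], axis=-1)


def gen_item_responses(
    traits: np.ndarray,
    params: dict[str, ItemParameters] | list[ItemParameters],
    seed: int = 0,
    cohort_ids: np.ndarray | None = None,
    person_ids: np.ndarray | None = None,
    link: str = "logistic",
) -> ResponseMatrix:
    """Draw graded-response ordinal codes for each person x item.

    Categories are sampled from the GRM category probabilities at each
    person's trait value, via inverse transform on per-cell uniforms.  The
    default logistic link matches the MML calibration engine; ``link=
    "probit"`` generates from the probit family used by the hierarchical
    invariance model (the two differ by the usual ~1.7 scale factor on
    discriminations).
    """
    if link not in ("logistic", "probit"):
        raise InvalidParameterError("link must be 'logistic' or 'probit'")
    traits = np.asarray(traits, dtype=float)
    if isinstance(params, dict):
        item_ids = list(params)
        plist = [params[i] for i in item_ids]
    else:
        plist = list(params)
        item_ids = [f"item{j + 1}" for j in range(len(plist))]
    rng = np.random.default_rng(seed)
    n = traits.size
    values = np.empty((n, len(plist)), dtype=np.int64)
    u = rng.random((n, len(plist)))
    for j, p in enumerate(plist):
        if link == "probit":
            probs = _probit_category_prob(traits, p)  # (n, K)
        else:
            probs = grm_category_prob(traits, p)  # (n, K)
        cum = np.cumsum(probs, axis=1)
        values[:, j] = (u[:, j][:, None] > cum[:, :-1]).sum(axis=1)
    if person_ids is None:
        person_ids = np.arange(n)
    if cohort_ids is None:
        cohort_ids = np.array(["C1"] * n)
    return ResponseMatrix(values, person_ids, item_ids, cohort_ids)


def gen_multi_inventory_design(
    responses: ResponseMatrix,
    inventories: dict[str, list[str]],
    bridge_fraction: float,
    seed: int = 0,
) -> ResponseMatrix:
    """Impose the bridge design: only a fixed fraction keeps >= 2 inventories.

    Per cohort, exactly ``floor(bridge_fraction * n)`` randomly chosen
    persons retain all inventories; everyone else keeps a single randomly
    assigned inventory.  The choice is independent of the latent trait, so
    the induced missingness is missing-at-random by construction.
    """
    if not 0.0 <= bridge_fraction <= 1.0:
        raise InvalidParameterError("bridge_fraction must lie in [0, 1]")
    inv_names = list(inventories)
    if bridge_fraction > 0 and len(inv_names) < 2:
        raise ConfigurationError("bridging requires at least two inventories")
    all_items = [i for items in inventories.values() for i in items]
    if sorted(all_items) != sorted(responses.item_ids):
        raise ConfigurationError("inventories must partition the item set")
    cols = {name: [responses.column(i) for i in items] for name, items in inventories.items()}

    rng = np.random.default_rng(seed)
    values = responses.values.copy()
    for cohort in np.unique(responses.cohort_ids):
        idx = np.flatnonzero(responses.cohort_ids == cohort)
        n = idx.size
        n_bridge = int(np.floor(bridge_fraction * n))
        perm = rng.permutation(n)
        solo = idx[perm[n_bridge:]]
        assigned = rng.integers(0, len(inv_names), size=solo.size)
        for k, name in enumerate(inv_names):
            drop_cols = [c for other, cc in cols.items() if other != name for c in cc]
            rows = solo[assigned == k]
            if rows.size and drop_cols:
                values[np.ix_(rows, drop_cols)] = MISSING
    return ResponseMatrix(values, responses.person_ids, responses.item_ids, responses.cohort_ids)


def gen_cohort_item_params(
    overall: dict[str, ItemParameters],
    n_cohorts: int,
    dif_sd: float = 0.0,
    dif_items: tuple[str, ...] = (),
    dif_shift: float = 0.0,
    seed: int = 0,
) -> list[dict[str, ItemParameters]]:
    """Perturb the overall item parameters per cohort (generating-side DIF).

    Thresholds receive independent normal noise with SD ``dif_sd`` (re-sorted
    to stay ordered) and log-discriminations normal noise with the same SD.
    Items listed in ``dif_items`` additionally have all thresholds shifted by
    ``+dif_shift`` in even-numbered cohorts and ``-dif_shift`` in odd ones,
    so the shift averages out across cohorts but the cross-cohort spread of
    that item's thresholds equals ``dif_shift``.
    """
    if dif_sd < 0:
        raise InvalidParameterError("dif_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    out: list[dict[str, ItemParameters]] = []
    for j in range(n_cohorts):
        sign = 1.0 if j % 2 == 0 else -1.0
        cohort_params: dict[str, ItemParameters] = {}
        for iid, p in overall.items():
            th = p.thresholds + dif_sd * rng.standard_normal(p.thresholds.size)
            loga = np.log(p.discrimination) + dif_sd * rng.standard_normal()
            if iid in dif_items:
                th = th + sign * dif_shift
            th = np.sort(th)
            th += 1e-9 * np.arange(th.size)  # guard exact ties after sorting
            cohort_params[iid] = ItemParameters(float(np.exp(loga)), th)
        out.append(cohort_params)
    return out


def gen_twin_pairs(config: TwinSimConfig) -> pd.DataFrame:
    """Generate twin-pair trait scores under the ADE covariance structure.

    Within each sex-by-zygosity group the pair of scores is bivariate normal
    with unit variances (before any age effect) and correlation
    ``h2 + d2`` (MZ), ``h2/2 + d2/4`` (same-sex DZ) or
    ``rg * (h_m h_f / 2 + d_m d_f / 4)`` (DOS), where ``h``/``d`` are path
    coefficients (square roots of the proportions) and ``rg`` the cross-sex
    genetic correlation multiplier.  A shared age effect is added to both
    members, and a fraction of pairs has one member's score removed.
    """
    rng = np.random.default_rng(config.seed)
    hm, hf = np.sqrt(config.h2_m), np.sqrt(config.h2_f)
    dm, df_ = np.sqrt(config.d2_m), np.sqrt(config.d2_f)
    rg = config.genetic_correlation_dos
    corr = {
        "MZM": config.h2_m + config.d2_m,
        "MZF": config.h2_f + config.d2_f,
        "DZM": 0.5 * config.h2_m + 0.25 * config.d2_m,
        "DZF": 0.5 * config.h2_f + 0.25 * config.d2_f,
        "DOS": rg * (0.5 * hm * hf + 0.25 * dm * df_),
    }
    rows = []
    for group, n_pairs in config.pairs_per_group.items():
        if n_pairs < 1:
            continue
        r = corr[group]
        z = rng.standard_normal((n_pairs, 2))
        s1 = z[:, 0]
        s2 = r * z[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * z[:, 1]
        lo, hi = config.age_range
        age = rng.uniform(lo, hi, size=n_pairs)
        s1 = s1 + config.age_slope * age
        s2 = s2 + config.age_slope * age
        s2 = s2.astype(float)
        n_miss = int(np.floor(config.missing_cotwin_fraction * n_pairs))
        if n_miss:
            miss = rng.choice(n_pairs, size=n_miss, replace=False)
            s2[miss] = np.nan
        rows.append(
            pd.DataFrame(
                {"cohort": config.cohort, "group": group, "age": age, "score1": s1, "score2": s2}
            )
        )
    if not rows:
        raise ConfigurationError("no twin groups with a positive pair count")
    return pd.concat(rows, ignore_index=True)


def gen_snp_phenotype(design: SnpDesign, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes under Hardy–Weinberg plus a latent trait they partly explain.

    The allelic effect is chosen so the genotype explains exactly ``q2`` of
    the latent-trait variance in expectation; the residual is normal with
    variance ``1 - q2`` so the trait has unit variance.
    """
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, design.maf, size=design.n).astype(float)
    var_g = 2.0 * design.maf * (1.0 - design.maf)
    beta = np.sqrt(design.q2 / var_g)
    trait = beta * (g - 2.0 * design.maf) + np.sqrt(1.0 - design.q2) * rng.standard_normal(design.n)
    return g, trait


# ---------------------------------------------------------------------------
# whole-study convenience generator
# ---------------------------------------------------------------------------


def default_item_bank(
    inventories: list[InventorySpec], seed: int = 0
) -> dict[str, ItemParameters]:
    """A realistic overall item bank: log-normal(0, 0.3^2) discriminations,
    thresholds evenly spread in [-2, 2] with small jitter."""
    rng = np.random.default_rng(seed)
    bank: dict[str, ItemParameters] = {}
    for inv in inventories:
        for j in range(inv.n_items):
            a = float(np.exp(0.3 * rng.standard_normal()))
            k = inv.n_categories
            base = np.linspace(-2.0, 2.0, k - 1) if k > 2 else np.array([0.0])
            shift = rng.uniform(-0.5, 0.5)
            th = np.sort(base + shift + 0.1 * rng.standard_normal(k - 1))
            th += 1e-9 * np.arange(th.size)
            bank[f"{inv.name}_{j + 1}"] = ItemParameters(a, th)
    return bank


@dataclass
class SimulatedStudy:
    """Everything the downstream stages need, from one seeded generator run."""

    responses: ResponseMatrix
    item_key: pd.DataFrame
    inventories: dict[str, list[str]]
    overall_params: dict[str, ItemParameters]
    cohort_params: list[dict[str, ItemParameters]]
    traits: np.ndarray


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generating model described by ``config``.

    Sub-streams for the item bank, traits, responses, DIF perturbations and
    the bridge design are spawned from the single study seed.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    overall = default_item_bank(config.inventories, seed=seeds[0])
    inventories = {
        inv.name: [f"{inv.name}_{j + 1}" for j in range(inv.n_items)] for inv in config.inventories
    }
    cohort_params = gen_cohort_item_params(
        overall,
        config.n_cohorts,
        dif_sd=config.dif_sd,
        dif_items=config.dif_items,
        dif_shift=config.dif_shift,
        seed=seeds[1],
    )

    blocks = []
    traits_all = []
    for j in range(config.n_cohorts):
        traits = gen_latent_traits(
            config.persons_per_cohort,
            config.cohort_trait_means[j],
            config.cohort_trait_variances[j],
            seed=seeds[2] + j,
        )
        resp = gen_item_responses(
            traits,
            cohort_params[j],
            seed=seeds[3] + j,
            cohort_ids=np.array([f"C{j + 1}"] * traits.size),
            person_ids=np.arange(traits.size) + j * config.persons_per_cohort,
        )
        blocks.append(resp)
        traits_all.append(traits)

    values = np.vstack([b.values for b in blocks])
    responses = ResponseMatrix(
        values,
        np.concatenate([b.person_ids for b in blocks]),
        blocks[0].item_ids,
        np.concatenate([b.cohort_ids for b in blocks]),
    )
    if len(config.inventories) > 1 and config.bridge_fraction < 1.0:
        responses = gen_multi_inventory_design(
            responses, inventories, config.bridge_fraction, seed=seeds[4]
        )

    key_rows = [
        {
            "item_id": iid,
            "inventory": inv.name,
            "trait": "trait",
            "n_categories": inv.n_categories,
            "reverse_keyed": 0,
        }
        for inv in config.inventories
        for iid in inventories[inv.name]
    ]
    return SimulatedStudy(
        responses=responses,
        item_key=pd.DataFrame(key_rows),
        inventories=inventories,
        overall_params=overall,
        cohort_params=cohort_params,
        traits=np.concatenate(traits_all),
    )
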