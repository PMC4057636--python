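"""GWAS power simulation for a latent-trait QTL under different phenotyping
schemes.

Each replicate draws genotypes and latent traits (the SNP explains a fixed
fraction ``q2`` of latent variance), generates graded item responses under a
scheme's item set and availability pattern, re-calibrates the measurement
model, EAP-scores every person, and tests the score-genotype association by
ordinary least squares with a Wald p-value.  Power is the proportion of
replicates with p below the significance threshold.

Because the IRT score is an error-contaminated version of the latent trait,
the non-centrality of the 1-df association test is approximately
``n * q2 * rho`` where ``rho`` is the squared correlation between score and
trait (the score reliability); richer item sets raise ``rho`` and larger
samples raise ``n``, which is the mechanism by which linking inventories
increases power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InvalidParameterError
from .irt_core import CalibrationOptions, ItemParameters, ResponseMatrix, calibrate_mml, score_eap
from .synthetic_data import SnpDesign, gen_item_responses, gen_snp_phenotype


@dataclass
class PowerScenario:
    """One phenotyping scheme for the power simulation.

    ``availability`` maps person fractions to item subsets: each entry
    ``(fraction, item_ids)`` assigns that fraction of the sample exactly
    those observed items (fractions must sum to 1).  A single entry with all
    items means everyone answers everything.
    """

    name: str
    item_params: dict[str, ItemParameters]
    availability: list[tuple[float, list[str]]]
    snp: SnpDesign
    alpha: float = 1e-8
    n_reps: int = 100
    seed: int = 0
    calib_options: CalibrationOptions = field(
        default_factory=lambda: CalibrationOptions(tol=5e-4, max_iter=200)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be at least 1")
        total = sum(f for f, _ in self.availability)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("availability fractions must sum to 1")
        for _, items in self.availability:
            unknown = [i for i in items if i not in self.item_params]
            if unknown:
                raise ConfigurationError(f"availability references unknown items {unknown}")


@dataclass
class PowerEstimate:
    """Estimated power with its binomial standard error."""

    name: str
    power: float
    se: float
    n_reps: int
    mean_reliability: float
    n: int


def _apply_availability(resp: ResponseMatrix, scenario: PowerScenario, rng) -> ResponseMatrix:
    n = resp.n_persons
    values = resp.values.copy()
    perm = rng.permutation(n)
    start = 0
    for frac, items in scenario.availability:
        stop = start + int(round(frac * n))
        rows = perm[start:stop]
        keep_cols = {resp.column(i) for i in items}
        drop_cols = [c for c in range(resp.n_items) if c not in keep_cols]
        if rows.size and drop_cols:
            values[np.ix_(rows, drop_cols)] = -1
        start = stop
    return ResponseMatrix(values, resp.person_ids, resp.item_ids, resp.cohort_ids)


def run_power_scenario(scenario: PowerScenario) -> PowerEstimate:
    """Simulate the full analysis chain and count genome-wide hits.

    The calibration is re-estimated in every replicate, matching a real
    analysis where item parameters are estimated from the same sample that
    is scored.  Persons left with zero observed items are scored at the
    prior mean (they stay in the regression; they simply carry no signal).
    """
    ss = np.random.SeedSequence(scenario.seed)
    n_hits = 0
    reliab = []
    for rep, child in enumerate(ss.spawn(scenario.n_reps)):
        s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3))
        geno, trait = gen_snp_phenotype(scenario.snp, seed=s1)
        resp = gen_item_responses(trait, scenario.item_params, seed=s2)
        rng = np.random.default_rng(s3)
        resp = _apply_availability(resp, scenario, rng)
        calib = calibrate_mml(resp, scenario.calib_options)
        scores = score_eap(resp, calib)
        res = stats.linregress(geno, scores.score)
        if res.pvalue < scenario.alpha:
            n_hits += 1
        reliab.append(float(np.corrcoef(scores.score, trait)[0, 1] ** 2))
    power = n_hits / scenario.n_reps
    se = float(np.sqrt(power * (1.0 - power) / scenario.n_reps))
    return PowerEstimate(
        name=scenario.name,
        power=power,
        se=se,
        n_reps=scenario.n_reps,
        mean_reliability=float(np.mean(reliab)),
        n=scenario.snp.n,
    )


def analytic_power(n: int, q2: float, reliability: float, alpha: float) -> float:
    """Non-centrality approximation: P(chi2_1(ncp = n q2 rho) > critical)."""
    ncp = n * q2 * reliability
    crit = stats.chi2.isf(alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


def compare_schemes(estimates: list[PowerEstimate]) -> list[dict]:
    """Side-by-side power table with pairwise differences against the first
    (baseline) scheme."""
    if len(estimates) < 2:
        raise ConfigurationError("need at least two scenarios to compare")
    base = estimates[0]
    rows = []
    for est in estimates:
        diff = est.power - base.power
        se_diff = float(np.sqrt(est.se**2 + base.se**2))
        rows.append(
            {
                "scheme": est.name,
                "n": est.n,
                "power": est.power,
                "se": est.se,
                "reliability": est.mean_reliability,
                "diff_vs_baseline": diff,
                "se_diff": se_diff,
            }
        )
    return rows
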