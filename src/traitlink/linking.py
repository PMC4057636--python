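"""Within-cohort test linking across inventories and its diagnostics.

Different inventories measuring the same trait are placed on one metric by a
single *concurrent* calibration: the graded-response model is fitted jointly
to the union of items, with the marginal likelihood integrating over each
person's observed items only.  This works whenever a "bridge" subsample was
assessed with two or more inventories, which ties the inventory-specific
item parameters to a common latent scale.

The diagnostics mirror standard practice for judging whether linking is
appropriate:

* scoring the same item set under a combined versus a single-inventory
  calibration and correlating the two score vectors (a correlation of 1
  means scores do not depend on which inventory supplied the calibration —
  local independence / unidimensionality);
* checking that the test information curve (TIC) of combined inventories
  behaves like the sum of the separate TICs;
* scoring one cohort's responses under another cohort's calibration and
  correlating (cross-cohort comparability);
* ranking candidate items by their correlation with a target scale's sum
  score, for assembling a linkable item subset from a related instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DisconnectedLinkingError, InsufficientDataError
from .irt_core import (
    Calibration,
    CalibrationOptions,
    ResponseMatrix,
    calibrate_mml,
    score_eap,
    test_information,
)


@dataclass
class LinkingDesign:
    """Which items belong to which inventory, and who holds what."""

    inventories: dict[str, list[str]]

    def availability(self, responses: ResponseMatrix) -> pd.DataFrame:
        """Person x inventory indicator of having >= 1 observed item."""
        out = {}
        for name, items in self.inventories.items():
            cols = [responses.column(i) for i in items]
            out[name] = (responses.values[:, cols] >= 0).any(axis=1)
        return pd.DataFrame(out, index=responses.person_ids)

    def bridge_mask(self, responses: ResponseMatrix) -> np.ndarray:
        """Persons observed on two or more inventories."""
        avail = self.availability(responses).to_numpy()
        return avail.sum(axis=1) >= 2

    def linking_graph(self, responses: ResponseMatrix) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.inventories)
        avail = self.availability(responses)
        names = list(self.inventories)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if int((avail[a] & avail[b]).sum()) > 0:
                    g.add_edge(a, b)
        return g


@dataclass
class CalibrationComparison:
    """Correlation between two score vectors for the same persons."""

    label_a: str
    label_b: str
    correlation: float
    n: int


def concurrent_calibration(
    responses: ResponseMatrix,
    design: LinkingDesign,
    options: CalibrationOptions | None = None,
) -> Calibration:
    """Joint GRM calibration over all inventories on one common metric.

    Requires every pair of inventories to be connected — directly or
    transitively — through bridge persons; otherwise the latent metric of a
    disconnected block would be arbitrary relative to the rest.
    """
    graph = design.linking_graph(responses)
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        raise DisconnectedLinkingError(
            "inventories not connected through bridge persons; components: "
            + "; ".join(sorted(",".join(sorted(c)) for c in components))
        )
    # sorted item order makes the result invariant to inventory labeling
    all_items = sorted(i for items in design.inventories.values() for i in items)
    opts = options or CalibrationOptions(complete_cases=False)
    return calibrate_mml(responses.subset_items(all_items), opts)


def local_independence_check(
    responses: ResponseMatrix,
    item_ids: list[str],
    combined_calib: Calibration,
    single_calib: Calibration,
) -> CalibrationComparison:
    """Correlate scores for one item set under two calibrations.

    Both calibrations must cover ``item_ids``; persons with zero observed
    items on the set are excluded.  A correlation near 1 indicates that
    scoring is independent of which calibration (inventory context) was
    used.
    """
    sub = responses.subset_items(item_ids)
    observed = (sub.values >= 0).any(axis=1)
    sub = sub.subset_persons(observed)
    if sub.n_persons < 3:
        raise InsufficientDataError("fewer than 3 persons with observed items to compare")
    s_comb = score_eap(sub, combined_calib)
    s_single = score_eap(sub, single_calib)
    r = float(stats.pearsonr(s_comb.score, s_single.score).statistic)
    return CalibrationComparison("combined", "single", r, sub.n_persons)


def tic_combination_check(
    combined_calib: Calibration,
    separate_calibs: dict[str, Calibration],
    itemsets: dict[str, list[str]],
    grid: np.ndarray | None = None,
) -> dict:
    """Compare the combined-calibration TIC with the sum of separate TICs.

    Under one latent dimension the information of the pooled test should be
    close to the sum of the separately calibrated tests; the report carries
    the maximum relative deviation over the grid region where the combined
    curve is appreciable (> 10% of its peak).
    """
    names = list(itemsets)
    seen: set[str] = set()
    for items in itemsets.values():
        overlap = seen.intersection(items)
        if overlap:
            raise ConfigurationError(f"itemsets overlap on {sorted(overlap)}")
        seen.update(items)
    if grid is None:
        grid = np.linspace(-3, 3, 61)
    combined = test_information(combined_calib, sorted(seen), grid)
    total_separate = np.zeros_like(grid)
    for name in names:
        total_separate += test_information(separate_calibs[name], itemsets[name], grid).information
    mask = combined.information > 0.1 * combined.information.max()
    rel = np.abs(combined.information - total_separate) / np.maximum(combined.information, 1e-12)
    return {
        "grid": grid,
        "combined": combined.information,
        "sum_separate": total_separate,
        "max_relative_deviation": float(rel[mask].max()),
    }


def cross_calibration_correlation(
    responses: ResponseMatrix,
    calib_a: Calibration,
    calib_b: Calibration,
    label_a: str = "A",
    label_b: str = "B",
) -> CalibrationComparison:
    """Score the same persons under two cohorts' calibrations and correlate."""
    missing_a = [i for i in responses.item_ids if i not in calib_a.items]
    missing_b = [i for i in responses.item_ids if i not in calib_b.items]
    if missing_a or missing_b:
        raise ConfigurationError(
            f"calibrations do not cover the scored items (missing: {missing_a + missing_b})"
        )
    observed = (responses.values >= 0).any(axis=1)
    sub = responses.subset_persons(observed)
    if sub.n_persons < 3:
        raise InsufficientDataError("fewer than 3 scored persons")
    sa = score_eap(sub, calib_a)
    sb = score_eap(sub, calib_b)
    r = float(stats.pearsonr(sa.score, sb.score).statistic)
    return CalibrationComparison(label_a, label_b, r, sub.n_persons)


def select_correlated_items(
    candidate_items: list[str],
    target_items: list[str],
    responses: ResponseMatrix,
    m: int,
) -> list[str]:
    """Top-m candidate items by correlation with the target-scale sum score.

    Pairwise-complete Pearson correlations between each candidate item's raw
    codes and the sum score over the target items; ties broken by item-id
    order.  This is how a related instrument's items can be screened for
    inclusion in a linking analysis.
    """
    if m > len(candidate_items):
        raise ConfigurationError(f"m={m} exceeds the {len(candidate_items)} candidates")
    tcols = [responses.column(i) for i in target_items]
    tvals = np.where(responses.values[:, tcols] >= 0, responses.values[:, tcols], np.nan)
    target_sum = np.nansum(tvals, axis=1)
    target_any = ~np.all(np.isnan(tvals), axis=1)

    scored = []
    for rank_tie, iid in enumerate(sorted(candidate_items)):
        col = responses.column(iid)
        y = responses.values[:, col].astype(float)
        ok = (y >= 0) & target_any
        if ok.sum() < 3:
            raise InsufficientDataError(f"item {iid!r}: fewer than 3 overlapping persons")
        r = float(stats.pearsonr(y[ok], target_sum[ok]).statistic)
        scored.append((-r, rank_tie, iid))
    scored.sort()
    return [iid for _, _, iid in scored[:m]]
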