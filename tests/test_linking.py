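"""Linking: concurrent calibration, score-comparison diagnostics, item
selection."""

import numpy as np
import pytest

import traitlink as tl
from traitlink.errors import (
    ConfigurationError,
    DisconnectedLinkingError,
    InsufficientDataError,
)
from traitlink.irt_core import calibrate_mml
from traitlink.linking import (
    LinkingDesign,
    concurrent_calibration,
    cross_calibration_correlation,
    local_independence_check,
    select_correlated_items,
    tic_combination_check,
)


@pytest.fixture(scope="module")
def linked(bridge_study):
    design = LinkingDesign(bridge_study.inventories)
    combined = concurrent_calibration(bridge_study.responses, design)
    return {"design": design, "combined": combined}


class TestConcurrentCalibration:
    def test_identical_calibrations_correlate_perfectly(self, bridge_study, linked):
        items = bridge_study.inventories["A"]
        cmp = local_independence_check(
            bridge_study.responses, items, linked["combined"], linked["combined"]
        )
        assert cmp.correlation == pytest.approx(1.0, abs=1e-12)

    def test_unidimensional_data_scores_inventory_independent(self, bridge_study, linked):
        """Scores for inventory-A items should barely depend on whether the
        calibration came from A alone or from the linked A+B pool."""
        items = bridge_study.inventories["A"]
        sub = bridge_study.responses.subset_items(items)
        single = calibrate_mml(sub)
        cmp = local_independence_check(bridge_study.responses, items, linked["combined"], single)
        assert cmp.correlation > 0.96

    def test_zero_bridge_raises_disconnected_error(self):
        cfg = tl.SimulationConfig(
            n_cohorts=1, persons_per_cohort=400,
            cohort_trait_means=[0.0], cohort_trait_variances=[1.0],
            inventories=[tl.InventorySpec("A", 4, 3), tl.InventorySpec("B", 4, 3)],
            bridge_fraction=0.0, seed=3,
        )
        study = tl.simulate_study(cfg)
        with pytest.raises(DisconnectedLinkingError):
            concurrent_calibration(study.responses, LinkingDesign(study.inventories))

    def test_bridge_persons_gain_precision_from_linking(self, bridge_study, linked):
        """A bridge person scored on both inventories has a smaller posterior
        SD under the combined calibration than under either single one."""
        design = linked["design"]
        bridge = design.bridge_mask(bridge_study.responses)
        sub_all = bridge_study.responses.subset_persons(bridge)
        sd_combined = tl.score_eap(sub_all, linked["combined"]).sd
        for inv in ("A", "B"):
            items = bridge_study.inventories[inv]
            single = calibrate_mml(bridge_study.responses.subset_items(items))
            sd_single = tl.score_eap(sub_all.subset_items(items), single).sd
            assert np.all(sd_combined <= sd_single + 1e-9)

    def test_inventory_label_permutation_leaves_scores_unchanged(self, bridge_study):
        design_swapped = LinkingDesign(
            {"B": bridge_study.inventories["B"], "A": bridge_study.inventories["A"]}
        )
        c1 = concurrent_calibration(bridge_study.responses, LinkingDesign(bridge_study.inventories))
        c2 = concurrent_calibration(bridge_study.responses, design_swapped)
        s1 = tl.score_eap(bridge_study.responses, c1)
        s2 = tl.score_eap(bridge_study.responses, c2)
        np.testing.assert_allclose(s1.score, s2.score, atol=1e-10)


class TestTicCombination:
    def test_overlapping_itemsets_rejected(self, bridge_study, linked):
        items = bridge_study.inventories
        with pytest.raises(ConfigurationError):
            tic_combination_check(
                linked["combined"],
                {"A": linked["combined"], "B": linked["combined"]},
                {"A": items["A"], "B": items["A"]},
            )

    def test_unidimensional_data_tics_nearly_additive(self, bridge_study, linked):
        singles = {
            inv: calibrate_mml(bridge_study.responses.subset_items(items))
            for inv, items in bridge_study.inventories.items()
        }
        report = tic_combination_check(linked["combined"], singles, bridge_study.inventories)
        assert report["max_relative_deviation"] <= 0.10
        # combined TIC dominates each separate subset under its own calibration
        for inv, items in bridge_study.inventories.items():
            part = tl.test_information(linked["combined"], items, report["grid"])
            assert np.all(report["combined"] >= part.information - 1e-12)


class TestCrossCalibration:
    def test_self_comparison_is_exactly_one(self, bridge_study, linked):
        cmp = cross_calibration_correlation(
            bridge_study.responses, linked["combined"], linked["combined"]
        )
        assert cmp.correlation == pytest.approx(1.0, abs=1e-12)

    def test_larger_dif_lowers_score_agreement(self, item_bank_12):
        """Scores under a perturbed 'other cohort' calibration degrade
        monotonically with the size of the parameter perturbation."""
        traits = tl.gen_latent_traits(1500, seed=41)
        resp = tl.gen_item_responses(traits, item_bank_12, seed=42)
        own = calibrate_mml(resp)
        results = {}
        for dif_sd in (0.2, 0.8):
            other_params = tl.gen_cohort_item_params(
                {i: own.items[i] for i in own.item_ids}, 1, dif_sd=dif_sd, seed=43
            )[0]
            other = tl.Calibration(items=other_params, category_maps=own.category_maps)
            cmp = cross_calibration_correlation(resp, own, other)
            results[dif_sd] = cmp.correlation
        assert results[0.2] > 0.95
        assert results[0.8] < results[0.2]

    def test_coverage_mismatch_rejected(self, bridge_study, linked):
        partial = tl.Calibration(
            items={i: linked["combined"].items[i] for i in bridge_study.inventories["A"]}
        )
        with pytest.raises(ConfigurationError):
            cross_calibration_correlation(bridge_study.responses, linked["combined"], partial)


class TestItemSelection:
    @pytest.fixture(scope="class")
    def loading_study(self):
        """Three candidate items with loadings 0.8 / 0.4 / 0.0 on the factor
        behind the target scale."""
        rng = np.random.default_rng(55)
        n = 2000
        factor = rng.standard_normal(n)
        target_items = {f"t{j}": tl.ItemParameters(1.5, [-0.5, 0.5]) for j in range(4)}
        resp_t = tl.gen_item_responses(factor, target_items, seed=56)
        cols = [resp_t.values]
        ids = list(target_items)
        for name, load in (("cand_hi", 0.8), ("cand_mid", 0.4), ("cand_null", 0.0)):
            x = load * factor + np.sqrt(1 - load**2) * rng.standard_normal(n)
            r = tl.gen_item_responses(x, {name: tl.ItemParameters(1.5, [0.0])}, seed=57)
            cols.append(r.values)
            ids.append(name)
        values = np.hstack(cols)
        return tl.ResponseMatrix(values, np.arange(n), ids, np.array(["C"] * n))

    def test_top_loading_candidates_selected(self, loading_study):
        chosen = select_correlated_items(
            ["cand_hi", "cand_mid", "cand_null"], ["t0", "t1", "t2", "t3"], loading_study, m=2
        )
        assert chosen == ["cand_hi", "cand_mid"]

    def test_all_candidates_returned_in_correlation_order(self, loading_study):
        chosen = select_correlated_items(
            ["cand_null", "cand_hi", "cand_mid"], ["t0", "t1", "t2", "t3"], loading_study, m=3
        )
        assert chosen == ["cand_hi", "cand_mid", "cand_null"]

    def test_m_larger_than_candidates_rejected(self, loading_study):
        with pytest.raises(ConfigurationError):
            select_correlated_items(["cand_hi"], ["t0"], loading_study, m=2)

    def test_target_item_itself_ranks_first(self, loading_study):
        chosen = select_correlated_items(
            ["t0", "cand_null"], ["t0", "t1", "t2", "t3"], loading_study, m=1
        )
        assert chosen == ["t0"]


class TestComparisonSymmetry:
    def test_cross_scoring_correlation_is_symmetric(self, bridge_study, linked):
        items = bridge_study.inventories["A"]
        sub = bridge_study.responses.subset_items(items)
        single = calibrate_mml(sub)
        ab = cross_calibration_correlation(sub, linked["combined"], single)
        ba = cross_calibration_correlation(sub, single, linked["combined"])
        assert ab.correlation == pytest.approx(ba.correlation, abs=1e-12)
        assert ab.n == ba.n
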