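"""Generator correctness: configured moments, determinism, design structure."""

import numpy as np
import pytest
from scipy import stats

import traitlink as tl
from traitlink.errors import ConfigurationError, InvalidParameterError


class TestLatentTraits:
    def test_moments_match_configuration(self):
        x = tl.gen_latent_traits(10_000, mean=0.0, variance=1.0, seed=1)
        se_mean = 1.0 / np.sqrt(10_000)
        se_var = np.sqrt(2.0 / 10_000)
        assert abs(x.mean()) < 4 * se_mean
        assert abs(x.var() - 1.0) < 4 * se_var

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            tl.gen_latent_traits(10, variance=0.0)

    def test_same_seed_identical(self):
        a = tl.gen_latent_traits(100, seed=5)
        b = tl.gen_latent_traits(100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestItemResponses:
    def test_saturating_item_always_top_category(self):
        p = {"x": tl.ItemParameters(1.0, [0.0])}
        resp = tl.gen_item_responses(np.full(200, 10.0), p, seed=2)
        assert resp.values.mean() > 0.999

    def test_zero_discrimination_independent_of_trait(self):
        """With a = 0 the response distribution cannot depend on the trait."""
        traits = tl.gen_latent_traits(5000, seed=3)
        p = {"x": tl.ItemParameters(0.0, [-1.0, 1.0])}
        resp = tl.gen_item_responses(traits, p, seed=4)
        low = traits < np.median(traits)
        table = np.array(
            [np.bincount(resp.values[low, 0], minlength=3),
             np.bincount(resp.values[~low, 0], minlength=3)]
        )
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.001

    def test_category_frequencies_match_model(self):
        """Monte-Carlo frequencies vs quadrature-integrated GRM probabilities."""
        n = 20_000
        p = tl.ItemParameters(1.5, [-1.0, 1.0])
        traits = tl.gen_latent_traits(n, seed=5)
        resp = tl.gen_item_responses(traits, {"x": p}, seed=6)
        observed = np.bincount(resp.values[:, 0], minlength=3) / n
        grid, w = np.linspace(-6, 6, 201), None
        dens = stats.norm.pdf(np.linspace(-6, 6, 201))
        w = dens / dens.sum()
        expected = w @ tl.grm_category_prob(np.linspace(-6, 6, 201), p)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(observed - expected) < 4 * se)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(InvalidParameterError):
            tl.ItemParameters(1.0, [1.0, -1.0])


class TestMultiInventoryDesign:
    def _study(self, bridge, n=1000, seed=9):
        cfg = tl.SimulationConfig(
            n_cohorts=1, persons_per_cohort=n,
            cohort_trait_means=[0.0], cohort_trait_variances=[1.0],
            inventories=[tl.InventorySpec("A", 4, 3), tl.InventorySpec("B", 4, 3)],
            bridge_fraction=bridge, seed=seed,
        )
        return tl.simulate_study(cfg)

    def test_full_bridge_means_no_extra_missingness(self):
        study = self._study(bridge=1.0)
        assert np.all(study.responses.values >= 0)

    def test_bridge_count_is_exact(self):
        study = self._study(bridge=0.3, n=1000)
        resp = study.responses
        a_cols = [resp.column(i) for i in study.inventories["A"]]
        b_cols = [resp.column(i) for i in study.inventories["B"]]
        both = ((resp.values[:, a_cols] >= 0).any(axis=1)
                & (resp.values[:, b_cols] >= 0).any(axis=1))
        assert both.sum() == 300

    def test_missingness_independent_of_trait(self):
        study = self._study(bridge=0.3, n=5000)
        missing_any = (study.responses.values < 0).any(axis=1).astype(float)
        r = np.corrcoef(missing_any, study.traits)[0, 1]
        assert abs(r) < 0.05

    def test_single_inventory_bridge_rejected(self):
        traits = tl.gen_latent_traits(50, seed=1)
        bank = {"A_1": tl.ItemParameters(1.0, [0.0])}
        resp = tl.gen_item_responses(traits, bank, seed=1)
        with pytest.raises(ConfigurationError):
            tl.gen_multi_inventory_design(resp, {"A": ["A_1"]}, bridge_fraction=0.3)


class TestCohortItemParams:
    def test_no_dif_gives_identical_cohorts(self, item_bank_12):
        sets = tl.gen_cohort_item_params(item_bank_12, 3, dif_sd=0.0, seed=1)
        for iid in item_bank_12:
            for s in sets:
                assert s[iid].discrimination == pytest.approx(item_bank_12[iid].discrimination)
                np.testing.assert_allclose(s[iid].thresholds, item_bank_12[iid].thresholds, atol=1e-8)

    def test_shifted_item_has_largest_cross_cohort_spread(self, item_bank_12):
        sets = tl.gen_cohort_item_params(
            item_bank_12, 5, dif_sd=0.05, dif_items=("i3",), dif_shift=0.5, seed=2
        )
        spreads = {}
        for iid in item_bank_12:
            means = [s[iid].thresholds.mean() for s in sets]
            spreads[iid] = np.std(means)
        assert max(spreads, key=spreads.get) == "i3"

    def test_perturbed_parameters_stay_valid(self, item_bank_12):
        sets = tl.gen_cohort_item_params(item_bank_12, 4, dif_sd=0.8, seed=3)
        for s in sets:
            for p in s.values():
                assert np.isfinite(p.discrimination) and p.discrimination > 0
                assert np.all(np.diff(p.thresholds) > 0)


class TestTwinPairs:
    def _corr(self, df, group):
        sub = df[df.group == group]
        ok = sub.score1.notna() & sub.score2.notna()
        return np.corrcoef(sub.score1[ok], sub.score2[ok])[0, 1]

    def test_mz_and_dz_correlations_match_ade_expectations(self):
        cfg = tl.TwinSimConfig(
            pairs_per_group={"MZM": 5000, "DZM": 5000}, h2_m=0.27, d2_m=0.21, seed=21
        )
        df = tl.gen_twin_pairs(cfg)
        se = (1 - 0.48**2) / np.sqrt(5000)
        assert abs(self._corr(df, "MZM") - 0.48) < 4 * se
        se = (1 - 0.1875**2) / np.sqrt(5000)
        assert abs(self._corr(df, "DZM") - 0.1875) < 4 * se

    def test_no_genetics_no_correlation(self):
        cfg = tl.TwinSimConfig(
            pairs_per_group={"MZF": 4000, "DZF": 4000}, h2_m=0.0, h2_f=0.0,
            d2_m=0.0, d2_f=0.0, seed=22,
        )
        df = tl.gen_twin_pairs(cfg)
        assert abs(self._corr(df, "MZF")) < 4 / np.sqrt(4000)
        assert abs(self._corr(df, "DZF")) < 4 / np.sqrt(4000)

    def test_unknown_group_rejected(self):
        with pytest.raises(ConfigurationError):
            tl.TwinSimConfig(pairs_per_group={"XYZ": 10})

    def test_invalid_proportions_rejected(self):
        with pytest.raises(InvalidParameterError):
            tl.TwinSimConfig(h2_m=0.8, d2_m=0.5)

    def test_missing_cotwin_fraction_applied(self):
        cfg = tl.TwinSimConfig(
            pairs_per_group={"MZM": 1000}, missing_cotwin_fraction=0.2, seed=23
        )
        df = tl.gen_twin_pairs(cfg)
        assert df.score2.isna().sum() == 200


class TestSnpPhenotype:
    def test_genotype_variance_under_hardy_weinberg(self):
        g, _ = tl.gen_snp_phenotype(tl.SnpDesign(maf=0.5, q2=0.001, n=50_000), seed=31)
        assert abs(g.var() - 0.5) < 4 * 0.5 * np.sqrt(2 / 50_000) * 2

    def test_null_snp_gives_alpha_level_significance(self):
        g, y = tl.gen_snp_phenotype(tl.SnpDesign(maf=0.3, q2=0.0, n=2000), seed=32)
        res = stats.linregress(g, y)
        assert res.pvalue > 0.001  # no signal expected

    def test_q2_is_the_explained_variance(self):
        g, y = tl.gen_snp_phenotype(tl.SnpDesign(maf=0.5, q2=0.001, n=1_000_000), seed=33)
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        se = 2 * np.sqrt(0.001) / np.sqrt(1_000_000)  # delta-method SE of r^2
        assert abs(r2 - 0.001) < 4 * se

    def test_invalid_maf_rejected(self):
        with pytest.raises(InvalidParameterError):
            tl.SnpDesign(maf=1.5, q2=0.1, n=10)


class TestDeterminism:
    @pytest.mark.parametrize("factory", [
        lambda s: tl.gen_latent_traits(50, seed=s),
        lambda s: tl.gen_item_responses(
            np.zeros(50), {"x": tl.ItemParameters(1.0, [0.0])}, seed=s
        ).values,
        lambda s: tl.gen_twin_pairs(
            tl.TwinSimConfig(pairs_per_group={"MZM": 30}, seed=s)
        ).to_numpy(),
        lambda s: tl.gen_snp_phenotype(tl.SnpDesign(n=40), seed=s)[0],
    ])
    def test_same_seed_bit_identical(self, factory):
        a, b = factory(9), factory(9)
        np.testing.assert_array_equal(np.asarray(a, dtype=object), np.asarray(b, dtype=object))
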