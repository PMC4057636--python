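"""Twin correlations and the ADE meta-analysis machinery."""

import numpy as np
import pandas as pd
import pytest

import traitlink as tl
from traitlink.errors import ConfigurationError
from traitlink.twin_meta import (
    ADEParameters,
    correlation_table,
    expected_twin_correlations,
    fit_ade_meta,
    fit_saturated_twin,
    lrt_sequence,
)


def table_from_params(params: ADEParameters, n: int = 2000, cohorts: int = 3) -> pd.DataFrame:
    """Exact model-implied correlation table (no sampling noise)."""
    rows = []
    for c in range(cohorts):
        for g in ("MZM", "DZM", "MZF", "DZF", "DOS"):
            rows.append(
                {"cohort": f"C{c}", "group": g, "trait": "t",
                 "r": expected_twin_correlations(params, g), "n": n}
            )
    return pd.DataFrame(rows)


class TestExpectedCorrelations:
    def test_mz_is_broad_sense_heritability(self):
        p = ADEParameters(np.sqrt(0.27), np.sqrt(0.27), np.sqrt(0.21), np.sqrt(0.21))
        assert expected_twin_correlations(p, "MZM") == pytest.approx(0.48)
        assert expected_twin_correlations(p, "DZM") == pytest.approx(0.1875)

    def test_null_genetics_gives_zero_everywhere(self):
        p = ADEParameters(0.0, 0.0, 0.0, 0.0)
        for g in ("MZM", "DZM", "MZF", "DZF", "DOS"):
            assert expected_twin_correlations(p, g) == 0.0

    def test_dos_equals_same_sex_dz_when_sexes_equal(self):
        p = ADEParameters(np.sqrt(0.3), np.sqrt(0.3), np.sqrt(0.2), np.sqrt(0.2))
        assert expected_twin_correlations(p, "DOS") == pytest.approx(
            expected_twin_correlations(p, "DZM")
        )

    def test_free_dos_overrides_expectation(self):
        p = ADEParameters(0.5, 0.5, 0.4, 0.4, r_dos_free=0.11)
        assert expected_twin_correlations(p, "DOS") == 0.11


class TestSaturatedFit:
    def test_parameter_count_with_and_without_dos(self):
        with_dos = tl.gen_twin_pairs(tl.TwinSimConfig(seed=1))
        assert fit_saturated_twin(with_dos).n_parameters == 16
        no_dos = tl.gen_twin_pairs(
            tl.TwinSimConfig(
                pairs_per_group={"MZM": 300, "DZM": 300, "MZF": 300, "DZF": 300}, seed=2
            )
        )
        assert fit_saturated_twin(no_dos).n_parameters == 13

    def test_ml_equals_moment_correlation_on_complete_data(self):
        """Without an age effect the ML correlation is the double-entry
        (intraclass-style) sample correlation, to optimizer precision."""
        df = tl.gen_twin_pairs(tl.TwinSimConfig(pairs_per_group={"MZM": 800}, seed=5))
        fit = fit_saturated_twin(df, fit_age=False)
        s1, s2 = df.score1.to_numpy(), df.score2.to_numpy()
        oracle = np.corrcoef(np.r_[s1, s2], np.r_[s2, s1])[0, 1]
        assert fit.groups["MZM"].correlation == pytest.approx(oracle, abs=1e-6)

    def test_age_slope_recovered(self):
        df = tl.gen_twin_pairs(
            tl.TwinSimConfig(pairs_per_group={"MZM": 2000, "DZF": 2000}, age_slope=0.02, seed=6)
        )
        fit = fit_saturated_twin(df)
        assert fit.age_slope == pytest.approx(0.02, abs=0.005)

    def test_incomplete_pairs_still_inform_means(self):
        df = tl.gen_twin_pairs(
            tl.TwinSimConfig(pairs_per_group={"MZM": 1500}, missing_cotwin_fraction=0.3, seed=7)
        )
        fit = fit_saturated_twin(df)
        est = fit.groups["MZM"]
        assert est.n_pairs == 1500
        assert est.n_complete == 1050
        assert abs(est.mean) < 0.1

    def test_ci_coverage_near_nominal(self):
        """95% CI for the MZ correlation should cover the truth in the large
        majority of replicates (binomial slack on 100 draws)."""
        hits = 0
        for rep in range(100):
            df = tl.gen_twin_pairs(
                tl.TwinSimConfig(pairs_per_group={"MZM": 4000}, h2_m=0.27, d2_m=0.21, seed=100 + rep)
            )
            est = fit_saturated_twin(df, fit_age=False).groups["MZM"]
            hits += est.ci_low <= 0.48 <= est.ci_high
        assert hits >= 90


class TestMetaFit:
    def test_perfect_table_recovered_exactly(self):
        truth = ADEParameters(np.sqrt(0.27), np.sqrt(0.27), np.sqrt(0.21), np.sqrt(0.21))
        table = table_from_params(truth)
        fit = fit_ade_meta(table, "no-quantitative")
        assert fit.chisq < 1e-6
        assert fit.params.h2_m == pytest.approx(0.27, abs=1e-6)
        assert fit.params.d2_m == pytest.approx(0.21, abs=1e-6)

    def test_perfect_table_recovered_exactly_fisher_z(self):
        truth = ADEParameters(0.5, 0.45, 0.45, 0.5, r_dos_free=0.12)
        table = table_from_params(truth)
        fit = fit_ade_meta(table, "base", discrepancy="fisher-z")
        assert fit.chisq < 1e-6
        assert fit.params.h2_m == pytest.approx(0.25, abs=1e-5)
        assert fit.params.r_dos_free == pytest.approx(0.12, abs=1e-5)

    def test_degrees_of_freedom_bookkeeping(self):
        table = table_from_params(ADEParameters(0.5, 0.5, 0.4, 0.4))
        rows = len(table)
        assert fit_ade_meta(table, "base").df == rows - 5
        assert fit_ade_meta(table, "no-qualitative").df == rows - 4
        assert fit_ade_meta(table, "no-quantitative").df == rows - 2
        assert fit_ade_meta(table, "no-quantitative", free_dos=True).df == rows - 3
        assert fit_ade_meta(table, "no-dominance").df == rows - 1

    def test_doubling_weights_doubles_chisq(self):
        """Both discrepancies are linear in the weights, so doubling every
        pair count doubles the minimized statistic for fixed correlations."""
        rng = np.random.default_rng(8)
        table = table_from_params(ADEParameters(0.5, 0.55, 0.45, 0.4, r_dos_free=0.15))
        table["r"] = np.clip(table["r"] + rng.normal(0, 0.03, len(table)), -0.9, 0.9)
        for disc in ("ml", "fisher-z"):
            f1 = fit_ade_meta(table, "no-quantitative", discrepancy=disc)
            t2 = table.copy()
            if disc == "fisher-z":
                t2["n"] = 2 * t2["n"] - 3  # weights are n - 3
            else:
                t2["n"] = 2 * t2["n"]
            f2 = fit_ade_meta(t2, "no-quantitative", discrepancy=disc)
            assert f2.chisq == pytest.approx(2 * f1.chisq, rel=1e-6)

    def test_unknown_model_label_rejected(self):
        table = table_from_params(ADEParameters(0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            fit_ade_meta(table, "ace")


class TestLrtSequence:
    def test_delta_df_bookkeeping(self):
        table = table_from_params(ADEParameters(0.5, 0.5, 0.45, 0.45))
        result = lrt_sequence(table)
        steps = {c["comparison"]: c for c in result["comparisons"]}
        assert steps["qualitative sex effects"]["delta_df"] == 1
        assert steps["quantitative sex effects"]["delta_df"] == 2

    def test_no_dominance_data_keeps_ae_model(self):
        """Simulated tables from an additive-only model: the dominance step
        should be non-significant in the large majority of replicates."""
        keep = 0
        n_reps = 50
        for rep in range(n_reps):
            table = _simulated_table(h2=0.45, d2=0.0, seed=300 + rep)
            result = lrt_sequence(table, discrepancy="fisher-z")
            dom = next(c for c in result["comparisons"] if c["comparison"] == "dominance variance")
            keep += not dom["significant"]
        assert keep >= int(0.9 * n_reps)

    def test_dominance_detected_at_consortium_scale(self):
        """With d2 = 0.2 at published-table sample sizes, dropping dominance
        must be rejected in nearly all replicates."""
        detected = 0
        n_reps = 50
        for rep in range(n_reps):
            table = _simulated_table(h2=0.27, d2=0.20, seed=600 + rep)
            result = lrt_sequence(table, discrepancy="fisher-z")
            dom = next(c for c in result["comparisons"] if c["comparison"] == "dominance variance")
            detected += dom["significant"]
        assert detected >= int(0.95 * n_reps)


def _simulated_table(h2: float, d2: float, seed: int) -> pd.DataFrame:
    """Correlation table simulated at the published table's sample sizes."""
    sizes = tl.load_table1_fixture("neuroticism")[["cohort", "group", "n"]]
    rows = []
    for k, (cohort, sub) in enumerate(sizes.groupby("cohort")):
        cfg = tl.TwinSimConfig(
            pairs_per_group={r.group: int(r.n) for r in sub.itertuples()},
            h2_m=h2, h2_f=h2, d2_m=d2, d2_f=d2, cohort=str(cohort), seed=seed * 31 + k,
        )
        fit = fit_saturated_twin(tl.gen_twin_pairs(cfg), fit_age=False)
        rows.append(fit)
    return correlation_table(rows)


class TestNesting:
    def test_restricted_models_never_fit_better_on_noise(self):
        rng = np.random.default_rng(9)
        for rep in range(5):
            table = table_from_params(
                ADEParameters(0.5, 0.45, 0.4, 0.45, r_dos_free=0.13), n=1500
            )
            table["r"] = np.clip(table["r"] + rng.normal(0, 0.05, len(table)), -0.9, 0.9)
            chain = [
                fit_ade_meta(table, "base"),
                fit_ade_meta(table, "no-qualitative"),
                fit_ade_meta(table, "no-quantitative"),
                fit_ade_meta(table, "no-dominance"),
            ]
            for parent, child in zip(chain, chain[1:]):
                assert child.chisq >= parent.chisq - 1e-8
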