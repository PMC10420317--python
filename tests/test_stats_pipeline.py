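import json

import numpy as np
import pandas as pd
import pytest

from certscore.core_model import Group
from certscore.stats_pipeline import (
    AnalysisConfig,
    kruskal_dunn,
    ols_multiple_regression,
    rank_ancova,
    risk_category_contingency,
    run_full_analysis,
    spearman_with_linfit,
)
from certscore.core_model import read_report, write_report
from certscore.synthetic_cohort import default_group_specs, generate_group


def three_group_frame(rng, n=30, shifts=(0.0, 0.0, 0.0), cov=None):
    frames = []
    for g, shift in zip(("NW", "OB-MetS-", "OB-MetS+"), shifts):
        x = rng.normal(shift, 1.0, n)
        frames.append(pd.DataFrame({"group": g, "y": x}))
    df = pd.concat(frames, ignore_index=True)
    if cov is not None:
        df["cov"] = cov(df, rng)
    return df


class TestKruskalDunn:
    def test_identical_values_degenerate(self):
        df = pd.DataFrame({"group": ["NW"] * 5 + ["OB-MetS-"] * 5, "y": 1.0})
        res = kruskal_dunn(df, "y")
        assert res.degenerate
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_null_simulation_type_one_error(self):
        rng = np.random.default_rng(11)
        keep = 0
        for _ in range(100):
            res = kruskal_dunn(three_group_frame(rng), "y")
            keep += res.p_value > 0.05
        assert keep >= 90

    def test_shifted_group_detected_in_all_pairs(self):
        rng = np.random.default_rng(12)
        df = three_group_frame(rng, n=30, shifts=(0.0, 0.0, 3.0))
        res = kruskal_dunn(df, "y")
        assert res.p_value < 0.001
        for pair in res.pairwise:
            involved = "OB-MetS+" in (pair["group_a"], pair["group_b"])
            if involved:
                assert pair["p_adjusted"] < 0.05

    def test_adjusted_p_dominates_raw(self, default_cohort_df):
        res = kruskal_dunn(default_cohort_df, "wc")
        for pair in res.pairwise:
            assert 0.0 <= pair["p_raw"] <= pair["p_adjusted"] <= 1.0
        assert len(res.pairwise) == 3  # all unordered group pairs

    def test_group_medians_reported(self, default_cohort_df):
        res = kruskal_dunn(default_cohort_df, "wc")
        assert set(res.summaries) == {"NW", "OB-MetS-", "OB-MetS+"}
        for s in res.summaries.values():
            assert s["q25"] <= s["median"] <= s["q75"]

    def test_too_small_group_rejected(self):
        df = pd.DataFrame({"group": ["NW", "NW", "OB-MetS-"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="OB-MetS-"):
            kruskal_dunn(df, "y")


class TestOlsRegression:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        df["y"] = 3.0 * df["a"] + 1.0
        res = ols_multiple_regression(df, "y", ["a", "b"])
        assert res.coefficients["a"]["coef"] == pytest.approx(3.0, abs=1e-10)
        assert res.coefficients["b"]["coef"] == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients["intercept"]["coef"] == pytest.approx(1.0, abs=1e-10)

    def test_insufficient_cases_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "a": [1.0, 2.0, 4.0], "b": [2.0, 1.0, 5.0]})
        with pytest.raises(ValueError, match="complete cases"):
            ols_multiple_regression(df, "y", ["a", "b"])

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(22)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = 2.0 * df["a"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            ols_multiple_regression(df, "y", ["a", "b"])


class TestRankAncova:
    def test_empty_covariates_reduces_to_unadjusted(self):
        rng = np.random.default_rng(31)
        df = three_group_frame(rng, shifts=(0.0, 1.0, 2.0))
        linear = rank_ancova(df, "y", [], method="rank_linear")
        quade = rank_ancova(df, "y", [], method="quade")
        for g in linear.contrasts:
            assert linear.contrasts[g]["estimate"] == pytest.approx(
                quade.contrasts[g]["estimate"], abs=1e-9
            )

    def test_null_covariate_concordance_with_unadjusted(self):
        rng = np.random.default_rng(32)
        agree = 0
        reps = 100
        for _ in range(reps):
            df = three_group_frame(
                rng, shifts=(0.0, 0.0, 1.2), cov=lambda d, r: r.normal(size=len(d))
            )
            unadj = rank_ancova(df, "y", [])
            adj = rank_ancova(df, "y", ["cov"])
            same = all(
                (unadj.contrasts[g]["p"] < 0.05) == (adj.contrasts[g]["p"] < 0.05)
                for g in unadj.contrasts
            )
            agree += same
        assert agree >= 90

    def test_full_mediation_removes_group_effect(self):
        """When groups differ only through the covariate, adjustment should
        absorb the whole group contrast."""
        rng = np.random.default_rng(33)
        reps = 100
        nonsig = {"OB-MetS-": 0, "OB-MetS+": 0}
        for _ in range(reps):
            cov = np.concatenate(
                [rng.normal(0, 1, 30), rng.normal(1.5, 1, 30), rng.normal(3, 1, 30)]
            )
            df = pd.DataFrame(
                {
                    "group": ["NW"] * 30 + ["OB-MetS-"] * 30 + ["OB-MetS+"] * 30,
                    "cov": cov,
                    # monotone in the covariate with homoscedastic noise; a
                    # strongly curved link would distort the rank-rank
                    # relation and inflate the contrast type-I error
                    "y": cov + rng.normal(0, 1, 90),
                }
            )
            adj = rank_ancova(df, "y", ["cov"])
            for g, c in adj.contrasts.items():
                nonsig[g] += c["p"] >= 0.05
        for g, count in nonsig.items():
            assert count >= 90, nonsig

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(34)
        df = three_group_frame(rng)
        df["cov"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            rank_ancova(df, "y", ["cov"])

    def test_missing_reference_group_rejected(self):
        rng = np.random.default_rng(35)
        df = three_group_frame(rng)
        with pytest.raises(ValueError, match="reference"):
            rank_ancova(df, "y", [], reference_group="XX")


class TestSpearmanWithLinfit:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = df["x"] ** 3
        res = spearman_with_linfit(df, "x", "y")
        assert res.rho == pytest.approx(1.0)
        df["y"] = -df["y"]
        assert spearman_with_linfit(df, "x", "y").rho == pytest.approx(-1.0)

    def test_line_recovery_under_noise(self):
        rng = np.random.default_rng(41)
        x = rng.uniform(0, 10, 84)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + 1.0 + rng.normal(0, 0.5, 84)})
        res = spearman_with_linfit(df, "x", "y")
        assert res.slope == pytest.approx(2.0, abs=0.1)
        assert res.intercept == pytest.approx(1.0, abs=0.5)
        assert res.rho_p < 1e-6

    def test_constant_input_flagged(self):
        df = pd.DataFrame({"x": [1.0] * 5, "y": [1.0, 2.0, 3.0, 4.0, 5.0]})
        res = spearman_with_linfit(df, "x", "y")
        assert res.constant_input and res.rho is None


class TestContingency:
    def test_df_always_six_for_three_by_four(self, default_cohort):
        from certscore.ceramide_scoring import score_cohort

        scored = score_cohort(default_cohort.to_dataframe())
        res = risk_category_contingency(scored)
        assert res.df == 6
        assert np.sum(res.table) == len(default_cohort)

    def test_identical_row_distributions_zero_statistic(self):
        df = pd.DataFrame(
            {
                "group": ["NW"] * 8 + ["OB-MetS-"] * 8,
                "category": (["low"] * 4 + ["moderate"] * 4) * 2,
            }
        )
        res = risk_category_contingency(df, exact="never")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_unassigned_group_rejected(self):
        df = pd.DataFrame({"group": [Group.UNASSIGNED.value] * 4, "category": ["low"] * 4})
        with pytest.raises(ValueError, match="UNASSIGNED"):
            risk_category_contingency(df)

    def test_monte_carlo_matches_pearson_on_large_counts(self):
        rng = np.random.default_rng(51)
        df = pd.DataFrame(
            {
                "group": rng.choice(["NW", "OB-MetS-", "OB-MetS+"], 400),
                "category": rng.choice(["low", "moderate", "increased", "high"], 400),
            }
        )
        pearson = risk_category_contingency(df, exact="never")
        mc = risk_category_contingency(df, exact="always", mc_permutations=2000, mc_seed=3)
        assert mc.method == "monte_carlo_exact"
        assert mc.p_value == pytest.approx(pearson.p_value, abs=0.06)


class TestRunFullAnalysis:
    def test_all_sections_populated(self, default_cohort):
        report = run_full_analysis(default_cohort)
        assert report.cert1_test is not None
        assert set(report.regressions) == set(AnalysisConfig().regression_outcomes)
        assert len(report.ancovas) == 4
        assert set(report.associations) == {"cert1~frs", "cert1~va"}
        assert report.contingency is not None
        assert report.group_tests  # per-variable battery ran
        assert not report.stage_errors

    def test_deterministic_given_cohort_and_config(self, default_cohort, tmp_path):
        a = run_full_analysis(default_cohort)
        b = run_full_analysis(default_cohort)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )
        path = write_report(a, tmp_path / "report.json")
        assert read_report(path) == a.to_dict()

    def test_single_group_cohort_degrades_gracefully(self):
        specs = default_group_specs()
        cohort = generate_group(specs["NW"], seed=3)
        report = run_full_analysis(cohort)
        # scoring stages succeed: reference + regressions present
        assert report.quartile_reference
        assert report.regressions
        # group comparison stages error with stage names
        assert any(k.startswith("group_test") for k in report.stage_errors)
        assert "contingency" in report.stage_errors

    def test_config_can_disable_ancova(self, default_cohort):
        report = run_full_analysis(default_cohort, AnalysisConfig(run_ancova=False))
        assert report.ancovas == []
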