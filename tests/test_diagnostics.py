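import math

import numpy as np
import pandas as pd
import pytest

from glycorisk import (ContingencyTable, adjusted_scores,
                       apply_marker_thresholds, compare_marker_vs_balance,
                       diagnostic_metrics, empirical_auc, rank_sum, roc_auc,
                       table2_fixtures)

from conftest import make_logratio_cohort


class TestThresholds:
    def test_ggt_men_upper_limit(self):
        assert apply_marker_thresholds("M", ggt=74.0)["GGT"] is True
        assert apply_marker_thresholds("M", ggt=73.0)["GGT"] is False

    def test_ggt_women_upper_limit(self):
        assert apply_marker_thresholds("F", ggt=39.0)["GGT"] is True
        assert apply_marker_thresholds("F", ggt=38.0)["GGT"] is False

    def test_cdt_boundary_negative(self):
        assert apply_marker_thresholds("F", cdt=1.6)["CDT"] is False
        assert apply_marker_thresholds("F", cdt=1.61)["CDT"] is True

    def test_mcv_boundary_negative(self):
        assert apply_marker_thresholds("M", mcv=100.0)["MCV"] is False
        assert apply_marker_thresholds("F", mcv=100.5)["MCV"] is True

    def test_missing_values_flag_none(self):
        flags = apply_marker_thresholds("M", ggt=50.0, mcv=float("nan"))
        assert flags["MCV"] is None and flags["CDT"] is None

    def test_rejects_unknown_sex(self):
        with pytest.raises(ValueError, match="sex"):
            apply_marker_thresholds("U", ggt=10)


class TestDiagnosticMetrics:
    """Published marker statistics, recomputed from the fixture counts."""

    def test_ggt_men(self):
        m = diagnostic_metrics(table2_fixtures()["GGT_men"])
        assert round(m.sensitivity, 1) == 18.2
        assert round(m.lr_plus, 2) == 2.03
        assert round(m.lr_ci[0], 2) == 1.30
        assert round(m.lr_ci[1], 2) == 3.15

    def test_cdt_men(self):
        m = diagnostic_metrics(table2_fixtures()["CDT_men"])
        assert round(m.sensitivity, 1) == 25.9
        assert round(m.specificity, 1) == 94.4
        assert round(m.lr_plus, 2) == 4.61
        assert round(m.lr_ci[0], 2) == 2.96
        assert round(m.lr_ci[1], 2) == 7.20

    def test_ggt_women(self):
        m = diagnostic_metrics(table2_fixtures()["GGT_women"])
        assert round(m.sensitivity, 1) == 32.0
        assert round(m.specificity, 1) == 91.2
        assert round(m.lr_plus, 2) == 3.65

    def test_cdt_women(self):
        m = diagnostic_metrics(table2_fixtures()["CDT_women"])
        assert round(m.specificity, 1) == 99.5
        assert round(m.lr_ci[0], 2) == 4.06

    def test_mcv_men_sensitivity_under_missingness_split(self):
        m = diagnostic_metrics(table2_fixtures()["MCV_men"])
        assert round(m.sensitivity, 1) == 7.1
        assert round(m.specificity, 1) == 98.7

    def test_perfect_test_flags_infinite_lr(self):
        m = diagnostic_metrics(ContingencyTable(tp=10, fn=0, fp=0, tn=10))
        assert m.sensitivity == 100.0 and m.specificity == 100.0
        assert math.isinf(m.lr_plus) and m.flag == "zero_fp"
        assert m.lr_ci is None

    def test_zero_tp_gives_zero_lr(self):
        m = diagnostic_metrics(ContingencyTable(tp=0, fn=10, fp=5, tn=5))
        assert m.lr_plus == 0.0 and m.flag == "zero_tp"

    def test_rejects_empty_margin(self):
        with pytest.raises(ValueError, match="margins"):
            diagnostic_metrics(ContingencyTable(tp=0, fn=0, fp=5, tn=5))

    def test_table_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(tp=-1, fn=1, fp=1, tn=1)


class TestRocAuc:
    def test_scores_equal_outcome(self):
        y = np.array([0, 0, 1, 1, 1])
        assert roc_auc(y.astype(float), y).auc == pytest.approx(1.0)

    def test_constant_scores(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(np.ones(4), y).auc == pytest.approx(0.5)

    def test_equals_rank_sum_u_statistic(self):
        # cross-module oracle: AUC == U / (n_pos * n_neg)
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        y = (rng.random(80) < 0.4).astype(int)
        u = rank_sum(scores[y == 1], scores[y == 0]).statistic
        auc = empirical_auc(scores, y)
        assert auc == pytest.approx(u / (y.sum() * (80 - y.sum())), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        a = roc_auc(scores, y).auc
        b = roc_auc(np.exp(scores), y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_swap_reflects_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        assert roc_auc(scores, 1 - y).auc == pytest.approx(
            1.0 - roc_auc(scores, y).auc, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=100)
        y = (rng.random(100) < 0.3).astype(int)
        r = roc_auc(scores, y)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert 0.0 <= r.ci95[0] and r.ci95[1] <= 1.0

    def test_null_mean_auc_near_half(self):
        rng = np.random.default_rng(10)
        aucs = []
        for _ in range(200):
            scores = rng.normal(size=200)
            y = np.repeat([0, 1], 100)
            aucs.append(empirical_auc(scores, y))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc(np.arange(5.0), np.ones(5))


class TestAdjustedScores:
    def test_intercept_only_returns_prevalence(self):
        df = make_logratio_cohort(n=100, seed=30)
        scores = adjusted_scores(df, [], [])
        prev = (df["risk"] == "risk").mean()
        np.testing.assert_allclose(scores, prev, atol=1e-6)

    def test_perfect_predictor_gives_auc_one(self):
        df = make_logratio_cohort(n=60, seed=31)
        df["perfect"] = (df["risk"] == "risk").astype(float)
        scores = adjusted_scores(df, ["perfect"], [])
        assert empirical_auc(scores, df["risk"]) == pytest.approx(1.0)

    def test_nested_model_never_lowers_in_sample_auc(self):
        for rep in range(5):
            df = make_logratio_cohort(n=300, seed=40 + rep)
            df["signal"] = np.log(df["GP01"]) - np.log(df["GP02"])
            base = adjusted_scores(df, [], ["age", "smoker"])
            full = adjusted_scores(df, ["signal"], ["age", "smoker"])
            auc_base = empirical_auc(base, df["risk"])
            auc_full = empirical_auc(full, df["risk"])
            assert auc_full >= auc_base - 1e-9


class TestCompareMarkerVsBalance:
    def test_identical_predictor_redundant(self):
        df = make_logratio_cohort(n=200, seed=50)
        df["marker"] = np.log(df["GP01"]) - np.log(df["GP02"])
        out = compare_marker_vs_balance(df, "marker", df["marker"].to_numpy(),
                                        covariates=("age", "smoker"))
        assert out["combined"].auc == pytest.approx(out["marker"].auc, abs=1e-6)

    def test_uninformative_balance_within_marker_ci(self):
        rng = np.random.default_rng(51)
        df = make_logratio_cohort(n=400, seed=51)
        df["marker"] = np.log(df["GP01"]) - np.log(df["GP02"])
        noise = rng.normal(size=len(df))
        out = compare_marker_vs_balance(df, "marker", noise,
                                        covariates=("age", "smoker"))
        lo, hi = out["marker"].ci95
        assert lo - 0.02 <= out["combined"].auc <= hi + 0.02

    def test_independent_effects_combine(self):
        wins = 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(600 + rep)
            n = 300
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            prob = 1 / (1 + np.exp(-(a + b)))
            y = (rng.random(n) < prob).astype(int)
            df = pd.DataFrame({"marker": a, "age": rng.normal(50, 8, n),
                               "smoker": (rng.random(n) < 0.3).astype(int),
                               "risk": np.where(y == 1, "risk", "non-risk")})
            out = compare_marker_vs_balance(df, "marker", b,
                                            covariates=("age", "smoker"))
            single_best = max(out["marker"].auc, out["balance"].auc)
            wins += out["combined"].auc >= single_best - 0.01
        assert wins / n_reps >= 0.95
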