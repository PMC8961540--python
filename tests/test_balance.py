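import numpy as np
import pandas as pd
import pytest

from glycorisk import (Balance, balance_score, evaluate_candidate,
                       forward_select, zero_replace)

from conftest import make_logratio_cohort, random_closed_composition


class TestBalanceScore:
    def test_single_part_log_ratio(self):
        gp = np.array([np.e * 2.0, 2.0, 5.0])
        assert balance_score(gp, [0], [1]) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_equal_parts_give_zero(self):
        gp = np.array([3.0, 3.0, 3.0, 3.0])
        assert balance_score(gp, [0, 1], [2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        gp = rng.lognormal(size=10)
        a = balance_score(gp, [0, 2], [5, 7, 9])
        b = balance_score(3.7 * gp, [0, 2], [5, 7, 9])
        assert a == pytest.approx(b, abs=1e-12)

    def test_permutation_invariance_within_sets(self):
        rng = np.random.default_rng(1)
        gp = rng.lognormal(size=8)
        assert balance_score(gp, [0, 1, 2], [5, 6]) == pytest.approx(
            balance_score(gp, [2, 0, 1], [6, 5]), abs=1e-12)

    def test_swap_negates_score(self):
        rng = np.random.default_rng(2)
        gp = rng.lognormal(size=12)
        a = balance_score(gp, [0, 3], [7, 8, 9])
        b = balance_score(gp, [7, 8, 9], [0, 3])
        assert a == pytest.approx(-b, abs=1e-12)

    def test_label_interface_matches_index_interface(self):
        rng = np.random.default_rng(3)
        comp = random_closed_composition(rng, n_parts=6, n_rows=5)
        df = pd.DataFrame(comp, columns=list("abcdef"))
        via_labels = balance_score(df, ["a", "c"], ["e"])
        via_index = balance_score(comp, [0, 2], [4])
        np.testing.assert_allclose(via_labels, via_index)

    def test_rejects_overlap_and_zeros(self):
        gp = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="disjoint"):
            balance_score(gp, [0, 1], [1, 2])
        gp0 = np.array([0.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="positive"):
            balance_score(gp0, [0], [1])

    def test_balance_dataclass_validates(self):
        with pytest.raises(ValueError, match="overlapping"):
            Balance(numerator=("GP1",), denominator=("GP1", "GP2"))
        with pytest.raises(ValueError, match="non-empty"):
            Balance(numerator=(), denominator=("GP2",))


class TestZeroReplace:
    def test_identity_on_positive_input(self):
        rng = np.random.default_rng(4)
        gp = random_closed_composition(rng, n_parts=10)
        np.testing.assert_array_equal(zero_replace(gp), gp)

    def test_pseudocount_arithmetic(self):
        gp = np.array([0.0, 40.0, 60.0])
        out = zero_replace(gp, method="pseudocount")
        delta = 20.0  # half the smallest positive value
        expected = np.array([delta, 40.0, 60.0]) * 100.0 / 120.0
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_multiplicative_preserves_ratios(self):
        gp = np.array([0.0, 10.0, 30.0, 60.0])
        out = zero_replace(gp, method="multiplicative")
        assert out[2] / out[1] == pytest.approx(3.0, abs=1e-12)
        assert out[3] / out[1] == pytest.approx(6.0, abs=1e-12)
        assert out.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(out > 0)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError, match="all-zero"):
            zero_replace(np.zeros(5))


class TestEvaluateCandidate:
    def test_constant_score_gives_half(self):
        df = make_logratio_cohort(n=80, seed=10)
        # equal numerator/denominator parts -> score 0 for every subject
        df2 = df.copy()
        df2["GP01"] = df2["GP02"]  # makes ln ratio exactly 0
        bal = Balance(numerator=("GP01",), denominator=("GP02",))
        assert evaluate_candidate(df2, bal) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        df = make_logratio_cohort(n=60, seed=11)
        order = np.argsort(np.log(df["GP01"]) - np.log(df["GP02"]))
        df = df.iloc[order].reset_index(drop=True)
        df["risk"] = ["non-risk"] * 30 + ["risk"] * 30
        bal = Balance(numerator=("GP01",), denominator=("GP02",))
        assert evaluate_candidate(df, bal) == pytest.approx(1.0)

    def test_true_pair_beats_random_pairs(self):
        df = make_logratio_cohort(n=400, num_peak=2, den_peak=7, seed=12)
        true_bal = Balance(numerator=("GP03",), denominator=("GP08",))
        true_crit = evaluate_candidate(df, true_bal)
        rng = np.random.default_rng(12)
        labels = [f"GP{i + 1:02d}" for i in range(12)]
        beaten = 0
        n_rand = 40
        for _ in range(n_rand):
            i, j = rng.choice(12, size=2, replace=False)
            if {i, j} == {2, 7}:
                continue
            crit = evaluate_candidate(
                df, Balance(numerator=(labels[i],), denominator=(labels[j],)))
            beaten += crit < true_crit
        assert beaten / n_rand >= 0.95


def brute_force_best_pair(df, covariates=()):
    """Independent oracle: exhaustive ordered-pair search using sklearn."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    labels = sorted(c for c in df.columns if c.startswith("GP"))
    y = (df["risk"] == "risk").astype(int).to_numpy()
    best, best_auc = None, -1.0
    for a in labels:
        for b in labels:
            if a == b:
                continue
            score = np.sqrt(0.5) * (np.log(df[a]) - np.log(df[b]))
            X = np.column_stack([score] + [df[c] for c in covariates])
            clf = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
            auc = roc_auc_score(y, clf.predict_proba(X)[:, 1])
            if auc > best_auc + 1e-10:
                best_auc, best = auc, (a, b)
    return best, best_auc


class TestForwardSelect:
    def test_matches_brute_force_pair_oracle(self):
        df = make_logratio_cohort(n=250, num_peak=4, den_peak=9, seed=21)
        res = forward_select(df, max_size=2, cv_folds=4, cv_repeats=1, seed=1)
        oracle_pair, oracle_auc = brute_force_best_pair(df)
        assert (res.balance.numerator[0], res.balance.denominator[0]) == oracle_pair
        assert res.criterion_trace[0] == pytest.approx(oracle_auc, abs=1e-6)

    def test_reproducible_given_seed(self):
        df = make_logratio_cohort(n=150, seed=22)
        a = forward_select(df, max_size=4, cv_folds=3, cv_repeats=2, seed=9)
        b = forward_select(df, max_size=4, cv_folds=3, cv_repeats=2, seed=9)
        assert a.balance == b.balance
        assert a.chosen_size == b.chosen_size
        assert a.cv_table == b.cv_table
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_training_trace_non_decreasing(self):
        df = make_logratio_cohort(n=300, seed=23)
        res = forward_select(df, max_size=5, cv_folds=3, cv_repeats=1, seed=3)
        trace = np.asarray(res.criterion_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_chosen_size_matches_balance(self):
        df = make_logratio_cohort(n=200, seed=24)
        res = forward_select(df, max_size=4, cv_folds=3, cv_repeats=1, seed=4)
        assert res.chosen_size == res.balance.size
        assert len(res.criterion_trace) == res.chosen_size - 1

    def test_recovery_smoke(self):
        hits = 0
        for rep in range(5):
            df = make_logratio_cohort(n=400, num_peak=0, den_peak=1,
                                      seed=100 + rep)
            res = forward_select(df, max_size=4, cv_folds=5, cv_repeats=1,
                                 seed=rep)
            hits += ("GP01" in res.balance.numerator
                     and "GP02" in res.balance.denominator)
        assert hits >= 4

    def test_covariates_are_used(self):
        df = make_logratio_cohort(n=200, seed=25)
        res = forward_select(df, covariates=("age", "smoker"), max_size=2,
                             cv_folds=3, cv_repeats=1, seed=5)
        assert res.covariates_used == ("age", "smoker")

    def test_rejects_max_size_above_peak_count(self):
        df = make_logratio_cohort(n=100, n_peaks=5, seed=26)
        with pytest.raises(ValueError, match="max_size"):
            forward_select(df, max_size=6, seed=1)

    def test_rejects_single_class_outcome(self):
        df = make_logratio_cohort(n=100, seed=27)
        df["risk"] = "risk"
        with pytest.raises(ValueError, match="both classes"):
            forward_select(df, max_size=2, cv_folds=3, cv_repeats=1, seed=1)
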