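"""Evaluation protocol: splitters, metrics, voting, CIs, signed-rank tests.

Metric formulas are cross-checked against scikit-learn recounts from raw
(truth, prediction) pairs; the exact Wilcoxon p-value is cross-checked
against exhaustive enumeration of all sign assignments.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn import metrics as skm

from eegtfr.evaluation import (ComparisonResult, ConfusionCounts,
                               compute_metrics, majority_vote,
                               make_image_folds, make_subject_folds,
                               per_channel_accuracy, subject_accuracy_ci,
                               wilcoxon_pairwise, wilcoxon_signed_rank)


class TestComputeMetrics:
    def test_hand_worked_confusion_table(self):
        m = compute_metrics(ConfusionCounts(TP=9, FP=1, TN=8, FN=2))
        assert m.accuracy == pytest.approx(85.00, abs=0.005)
        assert m.precision == pytest.approx(90.00, abs=0.005)
        assert m.recall == pytest.approx(81.82, abs=0.005)
        assert m.specificity == pytest.approx(88.89, abs=0.005)
        assert m.f1 == pytest.approx(85.71, abs=0.005)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=5, TN=7))
        assert all(v == 100.0 for v in m.as_dict().values())

    def test_zero_denominator_guard(self):
        with pytest.warns(UserWarning, match="recall"):
            m = compute_metrics(ConfusionCounts(TP=0, FN=0, TN=4, FP=0))
        assert m.recall == 0.0 and "recall" in m.undefined
        assert m.specificity == 100.0

    def test_thousand_random_tables_match_sklearn_recount(self, rng):
        """The five formulas agree with scikit-learn computed from expanded
        (truth, prediction) pairs for 1000 random confusion tables."""
        import warnings

        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, 4)
            if tp + tn + fp + fn == 0:
                continue
            truth = ["R"] * (tp + fn) + ["NR"] * (tn + fp)
            pred = (["R"] * tp + ["NR"] * fn) + (["NR"] * tn + ["R"] * fp)
            cm = ConfusionCounts.from_pairs(truth, pred)
            assert (cm.TP, cm.TN, cm.FP, cm.FN) == (tp, tn, fp, fn)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(cm)
            t = np.array(truth) == "R"
            p = np.array(pred) == "R"
            assert m.accuracy == pytest.approx(100 * skm.accuracy_score(t, p))
            assert m.precision == pytest.approx(
                100 * skm.precision_score(t, p, zero_division=0))
            assert m.recall == pytest.approx(
                100 * skm.recall_score(t, p, zero_division=0))
            assert m.specificity == pytest.approx(
                100 * skm.recall_score(~t, ~p, zero_division=0))
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    100 * skm.f1_score(t, p, zero_division=0))


class TestImageFolds:
    def test_balanced_cohort_fold_sizes(self):
        ids = [f"i{k}" for k in range(120)]
        labels = ["R"] * 60 + ["NR"] * 60
        plan = make_image_folds(ids, labels, seed=0)
        lab = dict(zip(ids, labels))
        for fold in plan.folds:
            assert sum(lab[i] == "R" for i in fold["test"]) == 10
            assert len(fold["test"]) == 20
            assert len(fold["train"]) == 90 and len(fold["val"]) == 10

    def test_exact_partition(self):
        ids = [f"i{k}" for k in range(137)]
        labels = (["R"] * 61 + ["NR"] * 76)
        plan = make_image_folds(ids, labels, seed=3)
        tests = [set(f["test"]) for f in plan.folds]
        assert set().union(*tests) == set(ids)
        for a, b in itertools.combinations(tests, 2):
            assert not (a & b)
        for f in plan.folds:
            assert not (set(f["train"]) | set(f["val"])) & set(f["test"])

    def test_stratification_within_one_image(self):
        ids = [f"i{k}" for k in range(100)]
        labels = ["R"] * 40 + ["NR"] * 60
        plan = make_image_folds(ids, labels, seed=1)
        lab = dict(zip(ids, labels))
        r_counts = [sum(lab[i] == "R" for i in f["test"]) for f in plan.folds]
        assert max(r_counts) - min(r_counts) <= 1

    def test_too_few_images_per_class(self):
        with pytest.raises(ValueError, match="class"):
            make_image_folds(list("abcdefg"), ["R"] * 3 + ["NR"] * 4)


class TestSubjectFolds:
    @pytest.mark.parametrize("n_r, n_nr, expected", [
        (12, 18, [(2, 3)] * 6),
        (23, 23, [(4, 4)] * 5 + [(3, 3)]),
    ])
    def test_cohort_compositions(self, n_r, n_nr, expected):
        ids = [f"R{i}" for i in range(n_r)] + [f"N{i}" for i in range(n_nr)]
        labels = ["R"] * n_r + ["NR"] * n_nr
        plan = make_subject_folds(ids, labels, seed=5)
        comp = [(sum(s.startswith("R") for s in f["test"]),
                 sum(s.startswith("N") for s in f["test"]))
                for f in plan.folds]
        assert comp == expected

    def test_no_subject_in_train_and_test_and_each_tested_once(self):
        ids = [f"R{i}" for i in range(12)] + [f"N{i}" for i in range(18)]
        labels = ["R"] * 12 + ["NR"] * 18
        plan = make_subject_folds(ids, labels, seed=2)
        seen = []
        for f in plan.folds:
            assert not set(f["train"]) & set(f["test"])
            assert not set(f["val"]) & set(f["test"])
            assert not set(f["train"]) & set(f["val"])
            seen.extend(f["test"])
        assert sorted(seen) == sorted(ids)

    def test_undersized_class_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="nearest"):
            make_subject_folds(["a", "b", "c", "x", "y", "z", "w", "v", "u"],
                               ["R"] * 3 + ["NR"] * 6)


class TestMajorityVote:
    def test_majority_and_tie_rules(self):
        votes, ties = majority_vote({
            "s1": ["R"] * 200 + ["NR"] * 180,
            "s2": ["R", "R"],
            "s3": ["R", "NR"],
        })
        assert votes == {"s1": "R", "s2": "R", "s3": "NR"}
        assert ties == 1

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError, match="no image"):
            majority_vote({"s": []})

    @given(st.lists(st.sampled_from(["R", "NR"]), min_size=1, max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_matches_sorted_mode(self, preds):
        votes, _ = majority_vote({"s": preds})
        counts = sorted(((preds.count(c), c) for c in set(preds)))
        if len(counts) == 2 and counts[0][0] == counts[1][0]:
            expected = "NR"
        else:
            expected = counts[-1][1]
        assert votes["s"] == expected


class TestSubjectAccuracyCI:
    def test_zero_variance(self):
        out = subject_accuracy_ci([80.0] * 6)
        assert out["mean"] == 80.0 and out["ci_low"] == out["ci_high"] == 80.0

    def test_mean_of_extremes(self):
        assert subject_accuracy_ci([100, 100, 100, 0, 0, 0])["mean"] == 50.0

    def test_matches_closed_form_t_interval(self, rng):
        acc = rng.uniform(60, 95, 6)
        out = subject_accuracy_ci(acc)
        lo, hi = stats.t.interval(0.95, df=5, loc=acc.mean(),
                                  scale=stats.sem(acc))
        assert out["ci_low"] == pytest.approx(lo)
        assert out["ci_high"] == pytest.approx(hi)

    def test_single_fold_is_na(self):
        out = subject_accuracy_ci([75.0])
        assert np.isnan(out["ci_low"]) and out["mean"] == 75.0


class TestPerChannelAccuracy:
    def test_effect_channels_rank_higher(self):
        truth = {f"s{i}": ("R" if i < 4 else "NR") for i in range(8)}
        preds = {}
        for ch in ["O1", "O2", "Cz"]:
            by_subj = {}
            for s, lbl in truth.items():
                if ch in ("O1", "O2"):
                    by_subj[s] = [lbl] * 5          # informative channel
                else:
                    by_subj[s] = ["R", "R", "R", "NR", "NR"]  # constant guess
            preds[ch] = by_subj
        out = per_channel_accuracy(preds, truth)
        assert out["O1"] == out["O2"] == 100.0
        assert out["Cz"] == 50.0

    def test_single_channel_equals_overall(self):
        truth = {"a": "R", "b": "NR"}
        out = per_channel_accuracy({"Cz": {"a": ["R"], "b": ["NR"]}}, truth)
        assert out == {"Cz": 100.0}

    def test_channel_without_images_is_nan(self):
        out = per_channel_accuracy({"Cz": {}}, {})
        assert np.isnan(out["Cz"])


def _enumeration_p(diffs):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, float)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


class TestWilcoxon:
    def test_six_all_positive_distinct_differences(self):
        a = np.array([10.0, 11, 12, 13, 14, 15])
        b = a - np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.03125)

    def test_identical_vectors_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank([1, 2, 3, 4, 5, 6],
                                        [1, 2, 3, 4, 5, 6]) == 1.0

    def test_two_sided_symmetry(self, rng):
        a = rng.uniform(0, 1, 6)
        b = rng.uniform(0, 1, 6)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank(b, a))

    @given(st.integers(5, 8), st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # distinct magnitudes, no zeros, random signs
        mags = np.sort(rng.uniform(0.1, 10, n)) + np.arange(n) * 1e-3
        signs = rng.choice([-1.0, 1.0], n)
        d = mags * signs
        b = rng.uniform(50, 90, n)
        a = b + d
        assert wilcoxon_signed_rank(a, b) == pytest.approx(_enumeration_p(d))

    def test_pairwise_table(self):
        table = {
            "resnet18": [99.4, 99.3, 99.5, 99.2, 99.4, 99.6],
            "mobilenet": [98.1, 98.0, 98.4, 97.9, 98.2, 98.3],
            "effnet": [97.9, 98.05, 98.3, 98.0, 98.15, 98.2],
        }
        results = wilcoxon_pairwise(table)
        assert len(results) == 3
        by_pair = {r.pair: r for r in results}
        assert by_pair[("resnet18", "mobilenet")].wilcoxon_p == pytest.approx(0.03125)
        assert by_pair[("resnet18", "mobilenet")].significant
        assert all(isinstance(r, ComparisonResult) for r in results)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="5"):
            wilcoxon_pairwise({"a": [1, 2], "b": [2, 3]})
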