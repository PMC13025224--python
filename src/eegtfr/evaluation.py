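"""Cross-validation splitting, confusion-matrix metrics, subject-level
majority voting with confidence intervals, per-channel analysis, and
pairwise Wilcoxon signed-rank model comparison.

Two complementary 6-fold strategies are supported:

* image-level — all images pooled and stratified by class, so images of
  one subject may fall on both sides of a fold (an upper-bound,
  image-discrimination estimate);
* subject-level — partitioned by subject so no patient contributes
  images to both training and testing of a fold (the clinically
  realistic estimate), with per-subject predictions obtained by
  majority voting over the subject's images.

The responder class is the positive class for all metrics.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "R"
TIE_BREAK_CLASS = "NR"   # conservative call on exact vote ties


@dataclass
class SplitPlan:
    """Fold assignments for one CV strategy.

    ``folds`` is a list of dicts with keys ``train``/``val``/``test``,
    each a list of unit identifiers (image IDs or subject IDs).
    """

    strategy: str                   # "image_level" | "subject_level"
    n_folds: int
    folds: list
    seed: int

    def test_sets(self):
        return [set(f["test"]) for f in self.folds]


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_pairs(cls, truth, predicted) -> "ConfusionCounts":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        pos = POSITIVE_CLASS
        return cls(
            TP=int(((truth == pos) & (predicted == pos)).sum()),
            TN=int(((truth != pos) & (predicted != pos)).sum()),
            FP=int(((truth != pos) & (predicted == pos)).sum()),
            FN=int(((truth == pos) & (predicted != pos)).sum()),
        )


@dataclass
class MetricSet:
    """Confusion-derived metrics as percentages in [0, 100]."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    undefined: list = field(default_factory=list)  # metrics hit a 0/0 guard

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("accuracy", "precision", "recall", "specificity", "f1")}


@dataclass
class ComparisonResult:
    pair: tuple
    accuracies_a: np.ndarray
    accuracies_b: np.ndarray
    wilcoxon_p: float
    significant: bool


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as 0")
        undefined.append(name)
        return 0.0
    return 100.0 * num / den


def compute_metrics(cm: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, specificity and F1 (percent)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list = []
    acc = 100.0 * (cm.TP + cm.TN) / cm.total
    prec = _ratio(cm.TP, cm.TP + cm.FP, "precision", undefined)
    rec = _ratio(cm.TP, cm.TP + cm.FN, "recall", undefined)
    spec = _ratio(cm.TN, cm.TN + cm.FP, "specificity", undefined)
    if prec + rec > 0:
        f1 = 2 * prec * rec / (prec + rec)   # already in percent
    else:
        f1 = _ratio(0, 0, "f1", undefined)
    return MetricSet(acc, prec, rec, spec, f1, undefined)


def make_image_folds(image_ids, labels, n_folds: int = 6,
                     val_frac: float = 0.10, seed: int = 0) -> SplitPlan:
    """Stratified image-level 6-fold plan with a 90/10 train/val split.

    The test folds partition the images exactly; within each fold the
    non-test images are split (stratified) into train and validation.
    """
    image_ids = np.asarray(image_ids, dtype=object)
    labels = np.asarray(labels)
    counts = Counter(labels)
    for cls, cnt in counts.items():
        if cnt < n_folds:
            raise ValueError(f"class {cls!r} has {cnt} images; need >= {n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for rest_idx, test_idx in skf.split(image_ids, labels):
        train_idx, val_idx = train_test_split(
            rest_idx, test_size=val_frac, stratify=labels[rest_idx],
            random_state=seed)
        folds.append({"train": list(image_ids[train_idx]),
                      "val": list(image_ids[val_idx]),
                      "test": list(image_ids[test_idx])})
    return SplitPlan("image_level", n_folds, folds, seed)


def _spread_counts(n: int, n_folds: int) -> list:
    """Split n units over folds as evenly as possible, remainder first."""
    base, rem = divmod(n, n_folds)
    return [base + (1 if f < rem else 0) for f in range(n_folds)]


def make_subject_folds(subject_ids, labels, n_folds: int = 6,
                       val_frac: float = 0.10, seed: int = 0) -> SplitPlan:
    """Subject-level 6-fold plan: every subject is tested exactly once.

    Each class is spread over the folds as evenly as possible, any
    remainder going to the earlier folds — so a 12R/18NR cohort tests
    (2R, 3NR) in every fold, and a 23R/23NR cohort tests (4R, 4NR) in
    folds 1-5 and (3R, 3NR) in fold 6.  The non-test subjects of each
    fold are split 90/10 into train and validation at subject
    granularity, stratified by class.
    """
    subject_ids = np.asarray(subject_ids, dtype=object)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    for cls in classes:
        n_cls = int((labels == cls).sum())
        if n_cls < n_folds:
            per = _spread_counts(n_cls, n_folds)
            raise ValueError(
                f"class {cls!r} has only {n_cls} subjects for {n_folds} folds; "
                f"nearest workable scheme would need >= {n_folds} per class "
                f"(got per-fold counts {per})"
            )
    rng = np.random.default_rng(seed)
    fold_members: list = [[] for _ in range(n_folds)]
    for cls in classes:
        members = subject_ids[labels == cls]
        members = members[rng.permutation(len(members))]
        counts = _spread_counts(len(members), n_folds)
        start = 0
        for f, c in enumerate(counts):
            fold_members[f].extend(members[start:start + c])
            start += c
    label_of = dict(zip(subject_ids, labels))
    folds = []
    for f in range(n_folds):
        test = list(fold_members[f])
        rest = [s for s in subject_ids if s not in set(test)]
        rest_labels = [label_of[s] for s in rest]
        train, val = train_test_split(rest, test_size=val_frac,
                                      stratify=rest_labels, random_state=seed)
        folds.append({"train": list(train), "val": list(val), "test": test})
    return SplitPlan("subject_level", n_folds, folds, seed)


def majority_vote(subject_image_predictions: dict) -> tuple:
    """Per-subject label by majority over the subject's image predictions.

    ``subject_image_predictions`` maps subject -> sequence of predicted
    class labels.  Exact ties break to the non-responder class (the
    clinically cautious call); the number of ties is returned alongside
    the per-subject labels.
    """
    votes = {}
    n_ties = 0
    for subject, preds in subject_image_predictions.items():
        preds = list(preds)
        if not preds:
            raise ValueError(f"subject {subject!r} has no image predictions")
        counts = Counter(preds)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            n_ties += 1
            votes[subject] = TIE_BREAK_CLASS
            logger.info("majority-vote tie for subject %s -> %s",
                        subject, TIE_BREAK_CLASS)
        else:
            votes[subject] = top[0][0]
    return votes, n_ties


def subject_accuracy_ci(fold_accuracies, confidence: float = 0.95) -> dict:
    """Mean, SD and t-based confidence interval over per-fold accuracies."""
    acc = np.asarray(fold_accuracies, dtype=float)
    if len(acc) < 2:
        return {"mean": float(acc.mean()) if len(acc) else float("nan"),
                "sd": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "n_folds": len(acc)}
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    sem = sd / np.sqrt(len(acc))
    tq = stats.t.ppf(0.5 + confidence / 2, df=len(acc) - 1)
    return {"mean": mean, "sd": sd, "ci_low": mean - tq * sem,
            "ci_high": mean + tq * sem, "n_folds": len(acc)}


def per_channel_accuracy(channel_image_predictions: dict, subject_truth: dict) -> dict:
    """Subject accuracy restricted to each channel's images.

    ``channel_image_predictions`` maps channel -> {subject -> predicted
    labels of that subject's images on that channel}; the result maps
    channel -> subject-level accuracy in percent (NaN for channels with
    no images).
    """
    out = {}
    for channel, by_subject in channel_image_predictions.items():
        if not by_subject:
            out[channel] = float("nan")
            continue
        votes, _ = majority_vote(by_subject)
        correct = sum(votes[s] == subject_truth[s] for s in votes)
        out[channel] = 100.0 * correct / len(votes)
    return out


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided exact signed-rank p-value for paired samples.

    Zero differences are dropped (standard signed-rank convention); if
    every difference is zero the test is degenerate and p = 1 is
    returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method="exact" if len(d) <= 25 else "auto")
    return float(res.pvalue)


def wilcoxon_pairwise(accuracy_table: dict, alpha: float = 0.05) -> list:
    """All unordered pairwise signed-rank comparisons of per-fold accuracies.

    ``accuracy_table`` maps a condition label (model or representation)
    to its per-fold accuracy vector; vectors must be paired (same folds,
    same order) and at least 5 folds long.
    """
    labels = list(accuracy_table)
    results = []
    for la, lb in itertools.combinations(labels, 2):
        a = np.asarray(accuracy_table[la], dtype=float)
        b = np.asarray(accuracy_table[lb], dtype=float)
        if len(a) != len(b):
            raise ValueError(f"unpaired fold vectors for {la!r} vs {lb!r}")
        if len(a) < 5:
            raise ValueError("need at least 5 paired folds per comparison")
        p = wilcoxon_signed_rank(a, b)
        results.append(ComparisonResult((la, lb), a, b, p, p < alpha))
    return results
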