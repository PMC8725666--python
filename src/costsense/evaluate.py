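"""Imbalance-aware metrics, the repeated stratified CV protocol, and paired statistics.

Metrics are computed from confusion counts with the conventions standard in
imbalanced learning: MCC and the geometric mean of sensitivity and
specificity (G-mean) are the headline measures, with the F-measure,
sensitivity, specificity and precision alongside.  Model assessment uses
5-fold stratified cross-validation repeated 4 times (20 partitions), and
paired comparisons across the 20 partition-level scores use the Wilcoxon
signed-rank test with step-down Holm-Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .arff_io import Dataset
from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVPlan",
    "WilcoxonResult",
    "ComparisonReport",
    "confusion_counts",
    "compute_metrics",
    "make_cv_plan",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
]

METRIC_NAMES = ("mcc", "g_mean", "f_measure", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts; their sum is the number of evaluated instances."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The six evaluation metrics derived from a confusion table."""

    mcc: float
    g_mean: float
    f_measure: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    """Confusion counts from boolean label vectors (True = positive class)."""
    yt = np.asarray(true_labels, dtype=bool)
    yp = np.asarray(predicted_labels, dtype=bool)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        fp=int(np.sum(~yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """All six metrics with the usual zero-denominator conventions.

    MCC := 0 when any confusion-table marginal is zero; the F-measure is 0
    when sensitivity + precision = 0; rates with an empty denominator are 0.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if counts.total == 0:
        raise ValidationError("cannot compute metrics from zero instances")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    g_mean = math.sqrt(sens * spec)
    f_measure = 2 * sens * prec / (sens + prec) if (sens + prec) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact int arithmetic
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(
        mcc=mcc,
        g_mean=g_mean,
        f_measure=f_measure,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
    )


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVPlan:
    """Stratified folds x repeats train/test partitions (folds*repeats total)."""

    folds: int
    repeats: int
    seed: int
    n_instances: int
    partitions: tuple  # of (train_idx, test_idx)

    @property
    def signature(self) -> tuple:
        """Identity of the plan, used to check that compared runs are paired."""
        return (self.folds, self.repeats, self.seed, self.n_instances)


def make_cv_plan(data: Dataset, folds: int = 5, repeats: int = 4, seed: int = 0) -> CVPlan:
    """Seeded stratified CV plan: per class, shuffle and deal round-robin.

    Within each repeat the test folds partition the instances and each
    fold's class proportions match the whole dataset within rounding.
    """
    if folds < 2 or repeats < 1:
        raise ValidationError("need folds >= 2 and repeats >= 1")
    if min(data.n_positive, data.n_negative) < folds:
        raise ValidationError(
            f"each class needs >= {folds} instances for {folds}-fold stratification; "
            f"minority has {data.n_positive} — use fewer folds"
        )
    rng = np.random.default_rng(seed)
    y = data.y
    all_idx = np.arange(data.n_instances)
    partitions = []
    for _ in range(repeats):
        fold_members = [[] for _ in range(folds)]
        # positive class first, then negative: fixed, documented order
        for cls_mask in (y, ~y):
            idx = all_idx[cls_mask].copy()
            rng.shuffle(idx)
            for pos, instance in enumerate(idx):
                fold_members[pos % folds].append(int(instance))
        for f in range(folds):
            test = np.sort(np.asarray(fold_members[f], dtype=int))
            train = np.setdiff1d(all_idx, test)
            partitions.append((train, test))
    return CVPlan(
        folds=folds,
        repeats=repeats,
        seed=seed,
        n_instances=data.n_instances,
        partitions=tuple(partitions),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided Wilcoxon signed-rank outcome."""

    p_value: float
    w_plus: float
    n_informative: int
    method: str  # "exact", "approx" or "degenerate"

    @property
    def all_zero(self) -> bool:
        return self.method == "degenerate"


def _exact_two_sided(ranks: np.ndarray, w_plus: float) -> float:
    """Exact null distribution of W+ by convolution over doubled mid-ranks."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(r2)
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (classic treatment) and ties among the
    absolute differences receive mid-ranks.  The exact null distribution is
    enumerated for up to 25 informative pairs; beyond that a normal
    approximation with continuity and tie correction is used.  When every
    difference is zero the test is degenerate and p = 1 is returned, flagged
    via ``method='degenerate'``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(p_value=1.0, w_plus=0.0, n_informative=0, method="degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return WilcoxonResult(
            p_value=_exact_two_sided(ranks, w_plus),
            w_plus=w_plus,
            n_informative=n,
            method="exact",
        )
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(p_value=1.0, w_plus=w_plus, n_informative=n, method="approx")
    # continuity correction of 0.5 toward the mean
    delta = w_plus - mu
    z = (abs(delta) - 0.5) / math.sqrt(var) if abs(delta) > 0.5 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return WilcoxonResult(p_value=p, w_plus=w_plus, n_informative=n, method="approx")


# ---------------------------------------------------------------------------
# Holm-Bonferroni step-down correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonReport:
    """Holm-Bonferroni step-down outcome over k hypotheses.

    ``rejected`` aligns with the input p-value order; ``order`` sorts the
    hypotheses from most to least significant, and ``thresholds`` are the
    step-down levels alpha/k, alpha/(k-1), ... in that sorted order.
    Rejections always form a prefix of the significance-ordered list.
    """

    p_values: tuple
    alpha: float
    order: tuple
    thresholds: tuple
    rejected: tuple
    labels: tuple = ()

    @property
    def k(self) -> int:
        return len(self.p_values)

    @property
    def n_rejected(self) -> int:
        return int(sum(self.rejected))


def holm_bonferroni(p_values, alpha: float = 0.05, labels=None) -> ComparisonReport:
    """Step-down Holm-Bonferroni: compare sorted p-values with alpha/k, alpha/(k-1), ...

    The procedure stops at the first sorted p-value that fails its
    threshold; all later hypotheses are retained.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValidationError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    k = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (k - np.arange(k))
    rejected = np.zeros(k, dtype=bool)
    for step, idx in enumerate(order):
        if p[idx] < thresholds[step]:
            rejected[idx] = True
        else:
            break
    if labels is None:
        labels = tuple(range(k))
    return ComparisonReport(
        p_values=tuple(float(v) for v in p),
        alpha=float(alpha),
        order=tuple(int(i) for i in order),
        thresholds=tuple(float(t) for t in thresholds),
        rejected=tuple(bool(r) for r in rejected),
        labels=tuple(labels),
    )
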