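"""Feature relevance ranking for two-class continuous data.

Six ranking heuristics are provided, spanning the univariate filters
(absolute Pearson correlation with the class indicator; information gain
and gain ratio on an MDL-discretized copy of each feature), the
multivariate filter ReliefF, and the embedded linear-SVM methods (single
fit, and recursive feature elimination).  Every ranker accepts per-instance
weights so that selection itself can be made cost-sensitive.

Weight semantics
----------------
Weights are normalized to mean 1 on entry, so uniformly scaled weights are
equivalent to no weighting at all.  For the moment/count-based rankers
(correlation, information gain, gain ratio) weighted statistics use weight
sums wherever the unweighted computation uses counts, which makes a run
with integer weights identical to a run on the instance-replicated dataset.
ReliefF follows the same replication semantics: each instance occupies
neighbour "slots" in proportion to its weight (including the extra copies
of the probe instance itself, which sit at distance zero), see
:func:`rank_relieff`.

Ties are broken everywhere by a stable sort — equal scores rank the lower
original feature index first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .arff_io import Dataset
from .exceptions import DegenerateInputError, SolverError, ValidationError

__all__ = [
    "RankedList",
    "InstanceWeights",
    "DiscretizationScheme",
    "SVMModel",
    "rank_correlation",
    "rank_info_gain",
    "rank_gain_ratio",
    "rank_relieff",
    "rank_svm_aw",
    "rank_svm_rfe",
    "cut_ranking",
    "mdl_cut_points",
    "RANKERS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedList:
    """A feature ranking: permutation of indices with non-increasing scores."""

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        order = np.asarray(self.order, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)
        n = len(order)
        if scores.shape != (n,):
            raise ValidationError("scores must align with order")
        if not np.array_equal(np.sort(order), np.arange(n)):
            raise ValidationError("order must be a permutation of 0..n-1")
        if n > 1 and np.any(np.diff(scores) > 0):
            raise ValidationError("scores must be non-increasing along the ranking")

    @property
    def n_features(self) -> int:
        return len(self.order)


class InstanceWeights:
    """Non-negative per-instance weights; uniform weights are a no-op."""

    def __init__(self, values):
        w = np.asarray(values, dtype=float)
        if w.ndim != 1:
            raise ValidationError("weights must be a 1-D vector")
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ValidationError("weights must be finite and non-negative")
        if not np.any(w > 0):
            raise ValidationError("at least one weight must be positive")
        self.values = w

    @classmethod
    def uniform(cls, n: int) -> "InstanceWeights":
        return cls(np.ones(n))

    def normalized(self) -> np.ndarray:
        """Weights rescaled to mean 1 (scale-invariant form)."""
        w = self.values
        return w / w.mean()

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-feature sorted cut points; an empty list collapses a feature to one bin."""

    cut_points: tuple

    def bin(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape, dtype=int)
        for j, cuts in enumerate(self.cut_points):
            out[:, j] = np.searchsorted(cuts, X[:, j], side="right")
        return out


@dataclass(frozen=True)
class SVMModel:
    """Linear decision function f(x) = w.x + b from a maximum-margin fit."""

    w: np.ndarray
    b: float
    reg: float


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _prepare(data: Dataset, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (X, y_bool, mean-1 weights); verify both classes carry weight."""
    if weights is None:
        weights = InstanceWeights.uniform(data.n_instances)
    elif not isinstance(weights, InstanceWeights):
        weights = InstanceWeights(weights)
    if len(weights) != data.n_instances:
        raise ValidationError("weights length must match the number of instances")
    u = weights.normalized()
    y = data.y
    if u[y].sum() == 0 or u[~y].sum() == 0:
        raise DegenerateInputError(
            "both classes must be represented with positive weight"
        )
    if np.count_nonzero(u) < 2:
        raise DegenerateInputError("need at least 2 instances with positive weight")
    return data.features, y, u


def _to_ranked(scores: np.ndarray) -> RankedList:
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")  # ties -> lower index first
    return RankedList(order=order, scores=scores[order])


def _entropy(counts: np.ndarray) -> float:
    """Entropy in bits of a (weighted) count vector, with 0*log0 := 0."""
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# CORR
# ---------------------------------------------------------------------------


def rank_correlation(data: Dataset, weights=None) -> RankedList:
    """Rank by |weighted Pearson correlation| with the 0/1 class indicator.

    Constant features (zero weighted variance) score 0.
    """
    X, y, u = _prepare(data, weights)
    yv = y.astype(float)
    sw = u.sum()
    mx = (u @ X) / sw
    my = (u @ yv) / sw
    Xc = X - mx
    yc = yv - my
    cov = (Xc.T @ (u * yc)) / sw
    varx = (u @ (Xc * Xc)) / sw
    vary = (u @ (yc * yc)) / sw
    denom = np.sqrt(varx * vary)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.abs(np.where(denom > 0, cov / denom, 0.0))
    return _to_ranked(np.nan_to_num(scores, nan=0.0))


# ---------------------------------------------------------------------------
# MDL discretization + IG / GR
# ---------------------------------------------------------------------------


def _mdl_recurse(values, c_pos, c_neg, lo, hi, cuts):
    """Fayyad-Irani recursive split of distinct-value range [lo, hi)."""
    pos = c_pos[lo:hi]
    neg = c_neg[lo:hi]
    Wp, Wn = pos.sum(), neg.sum()
    W = Wp + Wn
    if hi - lo < 2 or Wp == 0 or Wn == 0 or W <= 1:
        return
    ent_s = _entropy(np.array([Wp, Wn]))
    # candidate cuts between consecutive distinct values
    cp = np.cumsum(pos)[:-1]
    cn = np.cumsum(neg)[:-1]
    wl = cp + cn
    wr = W - wl
    with np.errstate(invalid="ignore", divide="ignore"):
        pl = np.where(cp > 0, cp / wl, 1.0)
        ql = np.where(cn > 0, cn / wl, 1.0)
        el = -(np.where(cp > 0, cp / wl * np.log2(pl), 0.0)
               + np.where(cn > 0, cn / wl * np.log2(ql), 0.0))
        pr = np.where((Wp - cp) > 0, (Wp - cp) / wr, 1.0)
        qr = np.where((Wn - cn) > 0, (Wn - cn) / wr, 1.0)
        er = -(np.where((Wp - cp) > 0, (Wp - cp) / wr * np.log2(pr), 0.0)
               + np.where((Wn - cn) > 0, (Wn - cn) / wr * np.log2(qr), 0.0))
    cond = (wl * el + wr * er) / W
    best = int(np.argmin(cond))  # ties -> leftmost cut
    gain = ent_s - cond[best]
    k = 2
    k1 = int(cp[best] > 0) + int(cn[best] > 0)
    k2 = int((Wp - cp[best]) > 0) + int((Wn - cn[best]) > 0)
    delta = math.log2(3.0**k - 2.0) - (k * ent_s - k1 * el[best] - k2 * er[best])
    threshold = (math.log2(W - 1.0) + delta) / W
    if gain <= threshold:
        return
    cut_idx = lo + best + 1  # split between distinct values cut_idx-1 | cut_idx
    cuts.append((values[cut_idx - 1] + values[cut_idx]) / 2.0)
    _mdl_recurse(values, c_pos, c_neg, lo, cut_idx, cuts)
    _mdl_recurse(values, c_pos, c_neg, cut_idx, hi, cuts)


def mdl_cut_points(x: np.ndarray, y: np.ndarray, u: np.ndarray) -> np.ndarray:
    """MDL-accepted cut points for one feature (weighted counts).

    Recursive entropy-minimizing binary splits, each accepted only when the
    information gain exceeds the minimum-description-length criterion
    ``(log2(N-1) + log2(3^k - 2) - [k*E - k1*E1 - k2*E2]) / N`` with N the
    total instance weight.  Returns a sorted (possibly empty) array.
    """
    mask = u > 0
    x, y, u = x[mask], y[mask], u[mask]
    order = np.argsort(x, kind="stable")
    xs, ys, us = x[order], y[order], u[order]
    values, start = np.unique(xs, return_index=True)
    if len(values) < 2:
        return np.empty(0)
    grp = np.searchsorted(values, xs)
    c_pos = np.bincount(grp, weights=us * ys, minlength=len(values))
    c_neg = np.bincount(grp, weights=us * (~ys), minlength=len(values))
    cuts: list[float] = []
    _mdl_recurse(values, c_pos, c_neg, 0, len(values), cuts)
    return np.sort(np.asarray(cuts))


def discretize(data: Dataset, weights=None) -> DiscretizationScheme:
    """Supervised MDL discretization of every feature."""
    X, y, u = _prepare(data, weights)
    return DiscretizationScheme(
        cut_points=tuple(mdl_cut_points(X[:, j], y, u) for j in range(X.shape[1]))
    )


def _ig_splitinfo(x_bins, y, u):
    """(information gain, split information) from bin ids for one feature."""
    nbins = int(x_bins.max()) + 1 if len(x_bins) else 1
    wp = np.bincount(x_bins, weights=u * y, minlength=nbins)
    wn = np.bincount(x_bins, weights=u * (~y), minlength=nbins)
    wb = wp + wn
    W = wb.sum()
    h_y = _entropy(np.array([wp.sum(), wn.sum()]))
    h_cond = 0.0
    for b in range(nbins):
        if wb[b] > 0:
            h_cond += wb[b] / W * _entropy(np.array([wp[b], wn[b]]))
    ig = max(0.0, h_y - h_cond)
    split_info = _entropy(wb)
    return ig, split_info


def rank_info_gain(data: Dataset, weights=None) -> RankedList:
    """Rank by information gain IG(X) = H(Y) - H(Y|X) in bits.

    Continuous features are first discretized with the supervised MDL
    procedure (weighted counts); features with no accepted cut point
    collapse to a single bin and score 0.
    """
    X, y, u = _prepare(data, weights)
    scheme = discretize(data, weights)
    bins = scheme.bin(X)
    scores = np.array([_ig_splitinfo(bins[:, j], y, u)[0] for j in range(X.shape[1])])
    return _to_ranked(scores)


def rank_gain_ratio(data: Dataset, weights=None) -> RankedList:
    """Rank by gain ratio GR(X) = IG(X) / SplitInfo(X) on the same discretization.

    SplitInfo compensates IG's bias toward finely split features; a single
    bin gives SplitInfo 0 and the score is 0 by convention.
    """
    X, y, u = _prepare(data, weights)
    scheme = discretize(data, weights)
    bins = scheme.bin(X)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        ig, si = _ig_splitinfo(bins[:, j], y, u)
        scores[j] = ig / si if si > 0 else 0.0
    return _to_ranked(scores)


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------


def rank_relieff(data: Dataset, weights=None, k_neighbors: int = 10) -> RankedList:
    """ReliefF relevance weights with every instance used as a probe (m = I).

    For each probe R_i the k nearest hits (same class) and k nearest misses
    (opposite class) are found under Manhattan distance on range-normalized
    features, and the feature weight is updated by
    ``W(X) := W(X) - diff(X, R_i, hits)/m + diff(X, R_i, misses)/m`` with
    diff averaged over the k neighbours;
    ``diff(X, a, b) = |a_X - b_X| / (max_X - min_X)``.

    Instance weights follow replication semantics: after normalizing the
    weights to mean 1, each neighbour occupies capacity ``u_j`` of the k
    slots (the probe itself occupies ``max(u_i - 1, 0)`` hit slots at
    distance zero, standing for its extra copies), and the probe's whole
    contribution is scaled by ``u_i``.  A run with mean-1 integer weights
    is therefore identical to the unweighted run on the dataset with each
    instance replicated ``u_i`` times; k is clamped to the available
    per-class capacity.
    """
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    X, y, u = _prepare(data, weights)
    n, D = X.shape
    # zero-weight instances stand for zero replicas: they do not define the range
    Xw = X[u > 0]
    lo, hi = Xw.min(axis=0), Xw.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Xn = (X - lo) / span

    dist = cdist(Xn, Xn, metric="cityblock")
    scores = np.zeros(D)
    k = float(k_neighbors)
    for i in range(n):
        if u[i] == 0:
            continue
        contrib = np.zeros(D)
        for same_class in (True, False):
            mask = (y == y[i]) if same_class else (y != y[i])
            idx = np.flatnonzero(mask & (u > 0))
            idx = idx[idx != i]
            cand_d = dist[i, idx]
            cand_cap = u[idx]
            if same_class and u[i] > 1:
                # the probe's own extra copies: zero-distance hits
                idx = np.append(i, idx)
                cand_d = np.append(0.0, cand_d)
                cand_cap = np.append(u[i] - 1.0, cand_cap)
            order = np.lexsort((idx, cand_d))
            avg = np.zeros(D)
            filled = 0.0
            for j in order:
                if filled >= k:
                    break
                take = min(cand_cap[j], k - filled)
                avg += take * np.abs(Xn[i] - Xn[idx[j]])
                filled += take
            if filled > 0:
                avg /= filled
            contrib += avg if not same_class else -avg
        scores += u[i] * contrib
    scores /= n
    return _to_ranked(scores)


# ---------------------------------------------------------------------------
# linear SVM (single fit and recursive elimination)
# ---------------------------------------------------------------------------


def _fit_linear_svm(X, y, u, reg):
    """Weighted linear SVM on internally standardized features.

    Features are standardized with weighted moments before fitting (|w| is
    scale-sensitive); the returned weight vector lives in the standardized
    space, which is what the ranking uses.
    """
    sw = u.sum()
    mean = (u @ X) / sw
    var = (u @ (X - mean) ** 2) / sw
    sd = np.sqrt(var)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    # tight tolerance: |w| must not depend on instance order at ranking precision
    clf = SVC(kernel="linear", C=reg, tol=1e-7)
    clf.fit(Xs, y.astype(int), sample_weight=u)
    if getattr(clf, "fit_status_", 0) != 0:
        raise SolverError(f"linear SVM failed to converge (libsvm status {clf.fit_status_})")
    w = np.asarray(clf.coef_).ravel()
    if not np.isfinite(w).all():
        raise SolverError("linear SVM produced non-finite weights")
    return SVMModel(w=w, b=float(clf.intercept_[0]), reg=reg)


def rank_svm_aw(data: Dataset, weights=None, reg: float = 1.0) -> RankedList:
    """Rank by |w_j| of a single weighted linear-SVM fit f(x) = w.x + b."""
    X, y, u = _prepare(data, weights)
    model = _fit_linear_svm(X, y, u, reg)
    return _to_ranked(np.abs(model.w))


def rank_svm_rfe(
    data: Dataset, weights=None, reg: float = 1.0, p_eliminate: float = 50.0
) -> RankedList:
    """SVM recursive feature elimination, removing ceil(p% of remaining) per round.

    Each round refits the SVM on the surviving features and moves the
    lowest-|w| batch to the tail of the ranking, ordered within the batch
    by the |w| of the round that removed them.  With p = 100% the whole
    ranking comes from a single fit and coincides with :func:`rank_svm_aw`.
    Scores are positional (n, n-1, ..., 1) since per-round |w| values are
    not comparable across rounds.
    """
    if not (0 < p_eliminate <= 100):
        raise ValidationError("p_eliminate must be in (0, 100]")
    X, y, u = _prepare(data, weights)
    n = X.shape[1]
    remaining = np.arange(n)
    batches: list[np.ndarray] = []
    while len(remaining):
        model = _fit_linear_svm(X[:, remaining], y, u, reg)
        absw = np.abs(model.w)
        ranked_round = remaining[np.argsort(-absw, kind="stable")]
        batch = max(1, math.ceil(p_eliminate / 100.0 * len(remaining)))
        batches.append(ranked_round[-batch:])
        remaining = np.sort(ranked_round[:-batch])
    order = np.concatenate(list(reversed(batches)))
    scores = np.arange(n, 0, -1, dtype=float)
    ranked = RankedList(order=order, scores=scores)
    return ranked


# ---------------------------------------------------------------------------
# cutting a ranking
# ---------------------------------------------------------------------------


def cut_ranking(ranked: RankedList, retain) -> np.ndarray:
    """First ceil(fraction * n) (float retain) or exactly `retain` (int) indices."""
    n = ranked.n_features
    if isinstance(retain, (bool, np.bool_)):
        raise ValidationError("retain must be a fraction or a count")
    if isinstance(retain, (int, np.integer)):
        k = int(retain)
        if not (0 < k <= n):
            raise ValidationError(f"retain count must be in 1..{n}, got {k}")
    else:
        f = float(retain)
        if not (0 < f <= 1):
            raise ValidationError(f"retain fraction must be in (0, 1], got {f}")
        # round before ceil to absorb float artefacts like 0.1*30 = 3.0000000004
        k = math.ceil(round(f * n, 9))
    return ranked.order[:k].copy()


RANKERS = {
    "corr": rank_correlation,
    "ig": rank_info_gain,
    "gr": rank_gain_ratio,
    "relieff": rank_relieff,
    "svm-aw": rank_svm_aw,
    "svm-rfe": rank_svm_rfe,
}
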