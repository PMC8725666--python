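"""Random-forest induction on a selected feature subset.

The base learner is a 100-tree random forest whose per-node split search
considers floor(log2(n)) + 1 random features, n being the number of input
features after selection.  Probability estimates P(+|x) are the averaged
per-tree leaf class proportions, which are smoother than raw vote fractions
— a relevant detail because the minimum-cost rule moves the decision
threshold.  The forest itself is delegated to scikit-learn; this module
pins down the contract (tree count, split candidates, instance-weight
support, probability semantics, seeding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .arff_io import Dataset
from .costs import CostMatrix, threshold_from_costs
from .exceptions import DegenerateInputError, ValidationError
from .ranking import InstanceWeights

__all__ = ["ForestConfig", "FittedForest", "split_candidates", "train_forest", "predict_default", "predict_min_cost"]


def split_candidates(n_features: int) -> int:
    """Number of random features tried per split: floor(log2(n)) + 1."""
    if n_features < 1:
        raise ValidationError("need at least one feature")
    return int(math.floor(math.log2(n_features))) + 1


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters: tree count (default 100) and RNG seed."""

    n_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


@dataclass
class FittedForest:
    """A fitted forest restricted to a feature subset."""

    estimator: RandomForestClassifier
    selected: np.ndarray
    n_input_features: int
    config: ForestConfig

    def _restrict(self, instances) -> np.ndarray:
        X = np.asarray(instances, dtype=float)
        if X.ndim != 2:
            raise ValidationError("instances must be a 2-D matrix")
        if X.shape[1] == len(self.selected):
            return X
        if X.shape[1] == self.n_input_features:
            return X[:, self.selected]
        raise ValidationError(
            f"instance dimensionality {X.shape[1]} matches neither the selection "
            f"({len(self.selected)}) nor the training space ({self.n_input_features})"
        )

    def predict_proba_positive(self, instances) -> np.ndarray:
        """P(+|x): averaged per-tree leaf class proportions."""
        X = self._restrict(instances)
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, pos_col]


def train_forest(
    data: Dataset,
    selected,
    weights: InstanceWeights | None = None,
    config: ForestConfig = ForestConfig(),
) -> FittedForest:
    """Fit the forest on ``data`` restricted to the ``selected`` feature indices.

    Instance weights are respected during induction (normalized to mean 1
    first, so uniformly scaled weights train the identical model under the
    same seed).  Identical seed and inputs give an identical model.
    """
    sel = np.asarray(selected, dtype=int)
    if sel.size == 0:
        raise ValidationError("selected feature set must be non-empty")
    if sel.min() < 0 or sel.max() >= data.n_features:
        raise ValidationError("selected indices out of range")
    y = data.y.astype(int)
    if weights is None:
        sw = None
        if len(np.unique(y)) < 2:
            raise DegenerateInputError("both classes must be present for training")
    else:
        u = weights.normalized()
        if u[y == 1].sum() == 0 or u[y == 0].sum() == 0:
            raise DegenerateInputError(
                "both classes must be present among positively-weighted instances"
            )
        # uniform weights are a no-op: take the exact unweighted code path so
        # the induced forest is bit-identical under the same seed
        sw = None if np.all(u == u[0]) else u
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=split_candidates(sel.size),
        random_state=config.seed,
    )
    clf.fit(data.features[:, sel], y, sample_weight=sw)
    return FittedForest(
        estimator=clf,
        selected=sel,
        n_input_features=data.n_features,
        config=config,
    )


def predict_default(model: FittedForest, instances) -> np.ndarray:
    """Cost-blind labels: positive iff P(+|x) >= 0.5 (tie -> positive)."""
    return model.predict_proba_positive(instances) >= 0.5


def predict_min_cost(model: FittedForest, instances, costs: CostMatrix) -> np.ndarray:
    """Minimum-expected-cost labels: positive iff P(+|x) >= pth(costs)."""
    return model.predict_proba_positive(instances) >= threshold_from_costs(costs)
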