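"""Misclassification costs and the two cost-sensitivity mechanisms.

A 2x2 cost matrix C(i, j) gives the cost of predicting class j for a
true-class-i instance.  By convention the false-negative cost C(+,-) is the
free parameter c, false positives cost C(-,+) = 1, and correct predictions
cost nothing.  Two equivalent mechanisms derive from the matrix:

* the minimum-expected-cost decision threshold
  pth = C(-,+) / (C(-,+) + C(+,-)), classifying positive when
  P(+|x) >= pth (ties go to the positive class), and
* instance weights proportional to each class's misclassification cost,
  rescaled so the total weight equals the number of instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arff_io import Dataset
from .exceptions import ValidationError
from .ranking import InstanceWeights

__all__ = ["CostMatrix", "ExpectedCosts", "threshold_from_costs", "expected_costs", "weights_from_costs"]


@dataclass(frozen=True)
class CostMatrix:
    """Binary misclassification costs: C(+,-) = fn_cost, C(-,+) = fp_cost.

    Off-diagonal costs must be positive; the diagonal (correct predictions)
    is fixed at zero — negative "rewards" are not supported.
    """

    fn_cost: float
    fp_cost: float = 1.0

    def __post_init__(self):
        if not (self.fn_cost > 0 and self.fp_cost > 0):
            raise ValidationError("off-diagonal costs must be positive")

    @classmethod
    def from_scalar(cls, c: float) -> "CostMatrix":
        """Cost matrix from the single false-negative cost c (unit FP cost)."""
        return cls(fn_cost=float(c), fp_cost=1.0)

    def as_table(self) -> np.ndarray:
        """C(i, j) with row/column order (positive, negative)."""
        return np.array([[0.0, self.fn_cost], [self.fp_cost, 0.0]])


@dataclass(frozen=True)
class ExpectedCosts:
    """Per-class conditional risks R(j|x) and the minimum-cost label."""

    risk_positive: float
    risk_negative: float
    label_positive: bool


def threshold_from_costs(costs: CostMatrix) -> float:
    """Probability threshold pth = C(-,+) / (C(-,+) + C(+,-)) in (0, 1)."""
    return costs.fp_cost / (costs.fp_cost + costs.fn_cost)


def expected_costs(p_pos: float, costs: CostMatrix) -> ExpectedCosts:
    """Conditional risks R(j|x) = sum_i P(i|x) C(i, j) and their argmin.

    R(+) = (1 - p_pos) * C(-,+) and R(-) = p_pos * C(+,-); a tie classifies
    positive, consistent with the >= in the threshold rule.
    """
    if not (0.0 <= p_pos <= 1.0):
        raise ValidationError("p_pos must be a probability")
    r_pos = (1.0 - p_pos) * costs.fp_cost
    r_neg = p_pos * costs.fn_cost
    return ExpectedCosts(risk_positive=r_pos, risk_negative=r_neg, label_positive=r_pos <= r_neg)


def weights_from_costs(data: Dataset, costs: CostMatrix) -> InstanceWeights:
    """Cost-proportional instance weights, rescaled to total mass I.

    Positives get raw weight C(+,-), negatives C(-,+); rescaling preserves
    the total instance mass so learner hyper-parameters stay comparable
    across cost settings.  Symmetric costs give uniform unit weights.
    """
    y = data.y
    raw = np.where(y, costs.fn_cost, costs.fp_cost)
    return InstanceWeights(raw * (data.n_instances / raw.sum()))
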