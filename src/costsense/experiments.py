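"""Orchestration of the cost-sensitive learning strategies over CV partitions.

Six learning strategies are compared:

``BASELINE``
    Random forest on all features, plain 0.5-threshold prediction.
``FS_MI``
    Feature selection (uniform weights) on the training split, then a
    plain forest — dimensionality reduction without cost-sensitivity.
``WFS_MI``
    Cost-sensitivity at the *selection* stage: features ranked under
    cost-proportional instance weights, forest trained unweighted.
``FS_WMI``
    Cost-sensitivity at the *model induction* stage via instance weights:
    uniform-weight selection, forest trained with cost-proportional weights.
``FS_MCMI``
    Cost-sensitivity at prediction time: uniform-weight selection, plain
    forest, minimum-expected-cost thresholding of P(+|x).
``ALLFEAT_MCMI``
    Minimum-cost thresholding without any feature selection.

Feature selection always happens inside each training fold — test
instances are never inspected during ranking or cutting.  One master seed
expands deterministically into the plan seed and one forest seed per
partition through ``numpy.random.SeedSequence(master, partition_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .arff_io import Dataset
from .classify import ForestConfig, predict_default, predict_min_cost, train_forest
from .costs import CostMatrix, weights_from_costs
from .evaluate import (
    METRIC_NAMES,
    ComparisonReport,
    CVPlan,
    MetricSet,
    compute_metrics,
    confusion_counts,
    holm_bonferroni,
    make_cv_plan,
    wilcoxon_signed_rank,
)
from .exceptions import ValidationError
from .ranking import RANKERS, cut_ranking

__all__ = [
    "Strategy",
    "StrategySpec",
    "RunResult",
    "StrategyComparison",
    "run_strategy",
    "compare_strategies",
    "results_table",
    "figure_sweep",
]


class Strategy(str, Enum):
    BASELINE = "BASELINE"
    FS_MI = "FS_MI"
    WFS_MI = "WFS_MI"
    FS_WMI = "FS_WMI"
    FS_MCMI = "FS_MCMI"
    ALLFEAT_MCMI = "ALLFEAT_MCMI"


_NEEDS_SELECTOR = {Strategy.FS_MI, Strategy.WFS_MI, Strategy.FS_WMI, Strategy.FS_MCMI}
_NEEDS_COST = {Strategy.WFS_MI, Strategy.FS_WMI, Strategy.FS_MCMI, Strategy.ALLFEAT_MCMI}


@dataclass(frozen=True)
class StrategySpec:
    """Which strategy to run, with its selector, retained fraction and cost c."""

    strategy: Strategy
    selector: str | None = None
    retain: float | None = None
    cost: float | None = None

    def __post_init__(self):
        strategy = Strategy(self.strategy)
        object.__setattr__(self, "strategy", strategy)
        if strategy in _NEEDS_SELECTOR:
            if self.selector not in RANKERS:
                raise ValidationError(
                    f"{strategy.value} needs a selector among {sorted(RANKERS)}"
                )
            if self.retain is None:
                raise ValidationError(f"{strategy.value} needs a retain fraction/count")
            if isinstance(self.retain, float) and not (0 < self.retain <= 1):
                raise ValidationError("retain fraction must be in (0, 1]")
        elif self.selector is not None or self.retain is not None:
            raise ValidationError(f"{strategy.value} does not take a selector/retain")
        if strategy in _NEEDS_COST:
            if self.cost is None or self.cost <= 0:
                raise ValidationError(f"{strategy.value} needs a positive cost c")
        elif self.cost is not None:
            raise ValidationError(f"{strategy.value} does not take a cost")

    def label(self) -> str:
        parts = [self.strategy.value]
        if self.selector is not None:
            parts.append(self.selector)
        if self.retain is not None:
            parts.append(f"retain={self.retain}")
        if self.cost is not None:
            parts.append(f"c={self.cost:g}")
        return "/".join(parts)


@dataclass(frozen=True)
class RunResult:
    """Per-partition metrics (folds x repeats entries) for one strategy run."""

    spec: StrategySpec
    per_partition: tuple  # of MetricSet
    selections: tuple  # of ndarray or None (BASELINE / ALLFEAT)
    plan_signature: tuple
    master_seed: int
    dataset_id: str = ""

    def metric_values(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise ValidationError(f"unknown metric {metric!r}")
        return np.array([getattr(m, metric) for m in self.per_partition])

    def mean(self, metric: str) -> float:
        return float(self.metric_values(metric).mean())

    def means(self) -> dict:
        return {m: self.mean(m) for m in METRIC_NAMES}


def _forest_seed(master_seed: int, partition_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(partition_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_strategy(
    data: Dataset,
    spec: StrategySpec,
    plan: CVPlan,
    n_trees: int = 100,
    master_seed: int | None = None,
    ranker_params: dict | None = None,
    dataset_id: str = "",
) -> RunResult:
    """Execute one strategy over every partition of the CV plan.

    Ranking, cutting, weighting and training all see the training split
    only; the test split is touched exclusively at prediction time.
    """
    if plan.n_instances != data.n_instances:
        raise ValidationError("plan was not built on this dataset")
    master = plan.seed if master_seed is None else master_seed
    params = ranker_params or {}
    costs = CostMatrix.from_scalar(spec.cost) if spec.cost is not None else None

    per_partition = []
    selections = []
    for p_idx, (train_idx, test_idx) in enumerate(plan.partitions):
        train = data.subset(train_idx)

        if spec.strategy in _NEEDS_SELECTOR:
            fs_weights = (
                weights_from_costs(train, costs)
                if spec.strategy is Strategy.WFS_MI
                else None
            )
            ranked = RANKERS[spec.selector](train, weights=fs_weights, **params)
            selected = cut_ranking(ranked, spec.retain)
        else:
            selected = np.arange(data.n_features)

        mi_weights = (
            weights_from_costs(train, costs) if spec.strategy is Strategy.FS_WMI else None
        )
        model = train_forest(
            train,
            selected,
            weights=mi_weights,
            config=ForestConfig(n_trees=n_trees, seed=_forest_seed(master, p_idx)),
        )
        X_test = data.features[test_idx]
        if spec.strategy in (Strategy.FS_MCMI, Strategy.ALLFEAT_MCMI):
            pred = predict_min_cost(model, X_test, costs)
        else:
            pred = predict_default(model, X_test)
        per_partition.append(compute_metrics(confusion_counts(data.y[test_idx], pred)))
        selections.append(selected if spec.strategy in _NEEDS_SELECTOR else None)

    return RunResult(
        spec=spec,
        per_partition=tuple(per_partition),
        selections=tuple(selections),
        plan_signature=plan.signature,
        master_seed=master,
        dataset_id=dataset_id,
    )


@dataclass(frozen=True)
class StrategyComparison:
    """Paired Wilcoxon + Holm comparison of candidate strategies vs a reference."""

    metric: str
    baseline_label: str
    baseline_mean: float
    labels: tuple
    means: tuple
    p_values: tuple
    report: ComparisonReport

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.labels,
                "mean": self.means,
                "p_value": self.p_values,
                "rejected": self.report.rejected,
            }
        )


def compare_strategies(
    results, baseline: RunResult, metric: str = "g_mean", alpha: float = 0.05
) -> StrategyComparison:
    """Wilcoxon signed-rank of each candidate vs the baseline, Holm-corrected.

    All runs must share the same CV plan so the 20 partition-level scores
    are paired; k equals the number of candidates.
    """
    results = list(results)
    if not results:
        raise ValidationError("need at least one candidate result")
    for r in results:
        if r.plan_signature != baseline.plan_signature:
            raise ValidationError("all compared runs must share the same CV plan")
    base_vals = baseline.metric_values(metric)
    p_values = []
    for r in results:
        p_values.append(wilcoxon_signed_rank(r.metric_values(metric), base_vals).p_value)
    labels = tuple(r.spec.label() for r in results)
    report = holm_bonferroni(p_values, alpha=alpha, labels=labels)
    return StrategyComparison(
        metric=metric,
        baseline_label=baseline.spec.label(),
        baseline_mean=baseline.mean(metric),
        labels=labels,
        means=tuple(r.mean(metric) for r in results),
        p_values=tuple(p_values),
        report=report,
    )


def results_table(results) -> pd.DataFrame:
    """One row per (strategy, partition) with all six metrics."""
    rows = []
    for r in results:
        for run_idx, m in enumerate(r.per_partition):
            row = {
                "dataset": r.dataset_id,
                "strategy": r.spec.strategy.value,
                "selector": r.spec.selector or "",
                "retain": "" if r.spec.retain is None else r.spec.retain,
                "c": "" if r.spec.cost is None else r.spec.cost,
                "run": run_idx,
            }
            row.update(m.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def figure_sweep(
    costs=(3, 4, 5),
    selectors=("corr", "svm-rfe"),
    retains=(0.0025, 0.005, 0.01, 0.02),
) -> list[StrategySpec]:
    """The default sweep grid: strategies x selectors x retained fractions x costs.

    Defaults mirror the benchmark protocol: retained fractions 0.25%-2% and
    false-negative costs per dataset (2-4 for mildly imbalanced data, 3-5
    for strongly imbalanced data; costs above 5 tend to buy sensitivity at
    an unprofitable false-positive price and are not part of the default
    grid, though nothing forbids them).
    """
    specs: list[StrategySpec] = [StrategySpec(Strategy.BASELINE)]
    for retain in retains:
        for sel in selectors:
            specs.append(StrategySpec(Strategy.FS_MI, selector=sel, retain=retain))
            for c in costs:
                specs.append(
                    StrategySpec(Strategy.WFS_MI, selector=sel, retain=retain, cost=c)
                )
                specs.append(
                    StrategySpec(Strategy.FS_WMI, selector=sel, retain=retain, cost=c)
                )
                specs.append(
                    StrategySpec(Strategy.FS_MCMI, selector=sel, retain=retain, cost=c)
                )
    for c in costs:
        specs.append(StrategySpec(Strategy.ALLFEAT_MCMI, cost=c))
    return specs
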