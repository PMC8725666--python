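"""Synthetic two-class, high-dimensional, imbalanced datasets.

The generator emulates the structure of gene-expression benchmarks used in
imbalanced classification studies: tens to hundreds of instances, thousands
of continuous features, a minority fraction below ~25%, and a small subset
of truly informative features.  The class-conditional model is Gaussian:
informative features are shifted by ``effect_size`` within-class standard
deviations in the positive (minority) class, optionally equicorrelated
within the informative block; the remaining features are pure noise,
independent of the class.

The single RNG stream per call is consumed in a fixed, documented order —
informative block, then noise block, then instance-order permutation — so
changing one part of the configuration does not silently shift unrelated
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arff_io import Dataset
from .exceptions import ValidationError

__all__ = ["SynthConfig", "SyntheticDataset", "generate"]

POSITIVE = "pos"
NEGATIVE = "neg"


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generator.

    Parameters
    ----------
    n_pos, n_neg : int
        Exact class counts; the positive class must be the minority.
    n_features : int
        Total dimensionality D.
    n_informative : int
        Number d <= D of class-informative features (the first d columns).
    effect_size : float
        Mean shift of informative features in the positive class, in units
        of the within-class standard deviation.
    noise_sd : float
        Within-class standard deviation sigma (default 1).
    block_rho : float
        Equicorrelation in [0, 1) within the informative block.
    seed : int
        RNG seed; identical seeds give bitwise-identical datasets.
    """

    n_pos: int
    n_neg: int
    n_features: int
    n_informative: int
    effect_size: float
    noise_sd: float = 1.0
    block_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("class counts must be positive")
        if self.n_pos > self.n_neg:
            raise ValidationError("positive class must be the minority (n_pos <= n_neg)")
        if not (0 < self.n_informative <= self.n_features):
            raise ValidationError("need 0 < n_informative <= n_features")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not (0 <= self.block_rho < 1):
            raise ValidationError("block_rho must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset plus its ground-truth informative feature indices."""

    data: Dataset
    informative: np.ndarray


def generate(config: SynthConfig) -> SyntheticDataset:
    """Draw a dataset from the Gaussian class-conditional model.

    The informative block uses the one-factor equicorrelation construction
    ``x = sqrt(rho) * z_shared + sqrt(1 - rho) * z_own`` (unit marginal
    variance), scaled by ``noise_sd``; positives are then shifted by
    ``effect_size * noise_sd`` in every informative feature.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    d, D = config.n_informative, config.n_features

    # 1) informative block
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, d))
    rho = config.block_rho
    block = (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own) * config.noise_sd

    # 2) noise block
    noise = rng.standard_normal((n, D - d)) * config.noise_sd

    features = np.concatenate([block, noise], axis=1)
    labels = np.array([POSITIVE] * config.n_pos + [NEGATIVE] * config.n_neg)
    features[: config.n_pos, :d] += config.effect_size * config.noise_sd

    # 3) instance-order permutation
    perm = rng.permutation(n)
    features = features[perm]
    labels = labels[perm]

    width = max(4, len(str(D)))
    names = tuple(f"f{i:0{width}d}" for i in range(D))
    data = Dataset(
        features=features,
        labels=labels,
        feature_names=names,
        positive_label=POSITIVE,
        class_values=(POSITIVE, NEGATIVE),
        relation=f"synthetic_seed{config.seed}",
    )
    return SyntheticDataset(data=data, informative=np.arange(d))
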