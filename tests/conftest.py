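import numpy as np
import pytest

from costsense import Dataset, SynthConfig, generate


def make_dataset(features, labels, positive="pos"):
    """Small helper: build a Dataset from raw arrays with default naming."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=str)
    values = [positive] + [v for v in dict.fromkeys(labels) if v != positive]
    return Dataset(
        features=features,
        labels=labels,
        feature_names=tuple(f"x{j}" for j in range(features.shape[1])),
        positive_label=positive,
        class_values=tuple(values),
    )


@pytest.fixture(scope="session")
def small_synth():
    """50 x 30 imbalanced dataset with 5 informative features (delta=1.5)."""
    return generate(
        SynthConfig(
            n_pos=10, n_neg=40, n_features=30, n_informative=5, effect_size=1.5, seed=3
        )
    )


@pytest.fixture
def relieff_toy():
    """1-D toy: values (0, 0.1 | 1.0, 0.9), classes (+,+ | -,-)."""
    return make_dataset([[0.0], [0.1], [1.0], [0.9]], ["pos", "pos", "neg", "neg"])


@pytest.fixture
def two_bin_toy():
    """X = (a,a,b,b) encoded 0/1, Y = (+,+,-,-): one perfect binary split."""
    return make_dataset([[0.0], [0.0], [1.0], [1.0]], ["pos", "pos", "neg", "neg"])
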