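"""Reading and writing two-class continuous-feature datasets in ARFF.

The canonical in-memory container is :class:`Dataset`: an ``instances x
features`` matrix of continuous values, one nominal class attribute with
exactly two values, and a designated *positive* class.  Following common
practice in imbalanced learning, the positive class is the minority class:
when no positive label is given explicitly the rarer class value is
designated positive, with ties broken by the first-declared nominal value.

Only the dense ARFF dialect is supported, and missing values ("?") are
rejected rather than imputed: the intended inputs are complete expression
matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import arff as _scipy_arff

from .exceptions import (
    ArffParseError,
    FeatureTypeError,
    MissingValueError,
    UnsupportedTaskError,
    ValidationError,
)

__all__ = ["Dataset", "read_arff", "write_arff"]


@dataclass(frozen=True)
class Dataset:
    """A two-class dataset of continuous features.

    Parameters
    ----------
    features : ndarray of shape (n_instances, n_features)
        Continuous feature matrix (float64, no missing entries).
    labels : ndarray of shape (n_instances,)
        Per-instance class value (strings).
    feature_names : tuple of str
        Unique feature names, one per column.
    positive_label : str
        The class value designated positive (conventionally the minority).
    class_values : tuple of two str
        The two class values in declared order (preserved through ARFF
        round-trips).
    relation : str
        ARFF relation name used when writing.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple
    positive_label: str
    class_values: tuple
    relation: str = "costsense"

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=str)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "class_values", tuple(self.class_values))
        if feats.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if labels.shape != (feats.shape[0],):
            raise ValidationError("labels length must match the number of instances")
        if not np.isfinite(feats).all():
            raise MissingValueError("feature matrix contains missing/non-finite entries")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        if len(self.feature_names) != feats.shape[1]:
            raise ValidationError("feature_names length must match the number of columns")
        present = set(np.unique(labels).tolist())
        if len(present) != 2:
            raise ValidationError(
                f"exactly two distinct class values must be present, got {sorted(present)}"
            )
        if len(self.class_values) != 2 or set(self.class_values) != present:
            raise ValidationError("class_values must list the two present class values")
        if self.positive_label not in present:
            raise ValidationError(f"positive_label {self.positive_label!r} not among class values")

    # -- basic accessors -------------------------------------------------

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def negative_label(self) -> str:
        a, b = self.class_values
        return b if self.positive_label == a else a

    @property
    def y(self) -> np.ndarray:
        """Boolean label vector, True for the positive (minority) class."""
        return self.labels == self.positive_label

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return self.n_instances - self.n_positive

    def subset(self, indices) -> "Dataset":
        """Row-subset the dataset (revalidates: both classes must remain)."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=self.feature_names,
            positive_label=self.positive_label,
            class_values=self.class_values,
            relation=self.relation,
        )

    def __eq__(self, other):
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
            and self.positive_label == other.positive_label
            and self.class_values == other.class_values
        )


def _designate_positive(labels, class_values, positive_label):
    counts = {v: int(np.sum(labels == v)) for v in class_values}
    if positive_label is not None:
        if positive_label not in class_values:
            raise ValidationError(
                f"positive_label {positive_label!r} is not a class value {class_values}"
            )
        if counts[positive_label] > counts[_other(class_values, positive_label)]:
            raise ValidationError(
                "requested positive class is the majority class; the positive class "
                "must be the minority by convention"
            )
        return positive_label
    # rarer class; ties broken by first-declared nominal value
    return min(class_values, key=lambda v: (counts[v], class_values.index(v)))


def _other(class_values, value):
    a, b = class_values
    return b if value == a else a


def read_arff(path, positive_label: str | None = None) -> Dataset:
    """Load a dense two-class ARFF file into a :class:`Dataset`.

    The file must declare numeric feature attributes plus exactly one
    nominal attribute (the class, in any position) with two values.  If
    ``positive_label`` is omitted the rarer class is designated positive.
    """
    path = Path(path)
    try:
        data, meta = _scipy_arff.loadarff(str(path))
    except _scipy_arff.ParseArffError as exc:
        raise ArffParseError(f"{path}: {exc}") from None
    except NotImplementedError as exc:
        raise FeatureTypeError(f"{path}: {exc}") from None
    except ValueError as exc:
        if "{" in str(exc):
            raise ArffParseError(
                f"{path}: sparse ARFF dialect is not supported (dense only)"
            ) from None
        raise ArffParseError(f"{path}: {exc}") from None

    names = list(meta.names())
    types = dict(zip(names, meta.types()))
    nominal = [n for n in names if types[n] == "nominal"]
    bad = [n for n in names if types[n] not in ("numeric", "nominal")]
    if bad:
        raise FeatureTypeError(f"non-numeric feature attribute(s): {bad}")
    if not nominal:
        raise UnsupportedTaskError("no nominal class attribute found")
    if len(nominal) > 1:
        raise FeatureTypeError(
            f"non-numeric feature attribute(s): {nominal[:-1]} "
            "(only one nominal attribute, the class, is supported)"
        )
    class_attr = nominal[0]
    class_values = tuple(v for v in meta[class_attr][1])
    if len(class_values) != 2:
        raise UnsupportedTaskError(
            f"class attribute {class_attr!r} has {len(class_values)} values; "
            "only binary tasks are supported"
        )

    feat_names = [n for n in names if n != class_attr]
    raw_labels = data[class_attr]
    labels = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in raw_labels])
    if "?" in labels:
        raise MissingValueError(f"{path}: missing class values are not supported")

    if feat_names:
        feats = np.column_stack([np.asarray(data[n], dtype=np.float64) for n in feat_names])
    else:
        feats = np.empty((len(labels), 0))
    if not np.isfinite(feats).all():
        rows, cols = np.where(~np.isfinite(feats))
        raise MissingValueError(
            f"{path}: missing value in attribute {feat_names[cols[0]]!r} "
            f"(instance {int(rows[0])}); missing values are rejected by policy"
        )

    present = np.unique(labels)
    if len(present) != 2:
        raise ValidationError(
            f"{path}: expected both class values present, found {present.tolist()}"
        )
    pos = _designate_positive(labels, class_values, positive_label)
    return Dataset(
        features=feats,
        labels=labels,
        feature_names=tuple(feat_names),
        positive_label=pos,
        class_values=class_values,
        relation=getattr(meta, "name", None) or path.stem,
    )


_NEEDS_QUOTE = re.compile(r"[\s,{}%'\"]")


def _quote(name: str) -> str:
    if name == "" or _NEEDS_QUOTE.search(name):
        return "'" + name.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return name


def _class_attr_name(feature_names) -> str:
    for cand in ("class", "Class", "target", "__class__"):
        if cand not in feature_names:
            return cand
    raise ValidationError("cannot find a free name for the class attribute")


def write_arff(data: Dataset, path) -> Path:
    """Write a :class:`Dataset` as dense ARFF; round-trips exactly.

    Values are written with full ``repr`` precision so that
    ``read_arff(write_arff(d))`` reproduces ``d`` bit for bit; the class
    attribute is written last with its values in declared order, so the
    minority-positive designation also survives the round-trip.
    """
    path = Path(path)
    class_attr = _class_attr_name(data.feature_names)
    lines = [f"@relation {_quote(data.relation)}", ""]
    for name in data.feature_names:
        lines.append(f"@attribute {_quote(name)} numeric")
    vals = ",".join(_quote(v) for v in data.class_values)
    lines.append(f"@attribute {_quote(class_attr)} {{{vals}}}")
    lines.append("")
    lines.append("@data")
    for row, lab in zip(data.features, data.labels):
        lines.append(",".join(repr(float(v)) for v in row) + "," + _quote(str(lab)))
    path.write_text("\n".join(lines) + "\n")
    return path
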