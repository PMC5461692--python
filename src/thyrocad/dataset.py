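"""Feature-matrix assembly, min-max normalization, group comparison, splits.

Feature columns are named by feature symbol plus filter-group index:
group 1 = wiener (W6), 2 = median (M6), 3 = average (A6), 4 = unfiltered
(non-filter); e.g. ``e1`` is entropy under the Wiener filter and ``k3`` the
kurtosis under the average filter.  Labels are +1 for nodule (the positive
class) and -1 for normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .features import FIRST_ORDER_NAMES, FeatureVector

__all__ = [
    "FeatureMatrix",
    "NormalizationParams",
    "GROUP_ORDER",
    "group_columns",
    "build_feature_matrix",
    "fit_min_max",
    "apply_min_max",
    "compare_groups_ttest",
    "split_selection_validation",
]

#: Group tag -> numeric suffix of its six feature columns.
GROUP_ORDER = {"W6": 1, "M6": 2, "A6": 3, "non-filter": 4}

LABEL_CODE = {"nodule": 1, "normal": -1}


def group_columns(group_tag: str) -> list[str]:
    """Six column names for one filter group, e.g. W6 -> e1,u1,m1,sd1,k1,s1."""
    idx = GROUP_ORDER[group_tag]
    return [f"{name}{idx}" for name in FIRST_ORDER_NAMES]


@dataclass
class FeatureMatrix:
    """Samples x named features, with +1/-1 labels and sample/patient ids."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    sample_ids: list[str]
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("labels length != number of samples")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length != number of columns")
        if not np.all(np.isin(self.labels, [-1, 1])):
            raise ValueError("labels must be +1 (nodule) or -1 (normal)")
        if not self.patient_ids:
            self.patient_ids = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.labels,
                             list(self.sample_ids), list(self.patient_ids))

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx], list(self.feature_names),
                             self.labels[idx],
                             [self.sample_ids[i] for i in idx],
                             [self.patient_ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "patient_id", self.patient_ids)
        df.insert(2, "label", ["nodule" if y > 0 else "normal" for y in self.labels])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = ["sample_id", "patient_id", "label"]
        feats = [c for c in df.columns if c not in meta]
        labels = np.array([LABEL_CODE[l] for l in df["label"]])
        return cls(df[feats].to_numpy(float), feats, labels,
                   [str(s) for s in df["sample_id"]],
                   [str(p) for p in df["patient_id"]])


def build_feature_matrix(per_group: dict[str, list[FeatureVector]],
                         labels: list[str],
                         sample_ids: list[str],
                         subset_spec: list[str],
                         patient_ids: list[str] | None = None) -> FeatureMatrix:
    """Concatenate per-filter-group feature vectors into one matrix.

    ``per_group`` maps group tag (W6/M6/A6/non-filter) to one FeatureVector
    per sample; ``subset_spec`` lists the groups to include, in order.
    """
    n = len(labels)
    for tag in subset_spec:
        if tag not in per_group:
            raise ValueError(f"feature group {tag!r} was not computed")
        if len(per_group[tag]) != n:
            raise ValueError(f"group {tag!r} has {len(per_group[tag])} vectors for {n} samples")
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for tag in subset_spec:
        cols.extend(group_columns(tag))
        blocks.append(np.array(
            [[fv.as_dict()[name] for name in FIRST_ORDER_NAMES] for fv in per_group[tag]]
        ))
    values = np.hstack(blocks)
    y = np.array([LABEL_CODE[l] for l in labels])
    return FeatureMatrix(values, cols, y, list(sample_ids),
                         list(patient_ids) if patient_ids else [])


@dataclass
class NormalizationParams:
    """Per-feature min and max of the fitted data (the min-max rescaling)."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs == self.mins


def fit_min_max(matrix: FeatureMatrix) -> NormalizationParams:
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit normalization")
    return NormalizationParams(mins=matrix.values.min(axis=0),
                               maxs=matrix.values.max(axis=0))


def apply_min_max(matrix: FeatureMatrix, params: NormalizationParams,
                  clip_log: dict | None = None) -> FeatureMatrix:
    """Rescale each feature to [0, 1]: ``Y = (X - min) / (max - min)``.

    Constant (degenerate) columns map to 0.  Values beyond the fitted range
    (validation samples outside the training min/max) are clipped to [0, 1];
    the clip count is recorded in ``clip_log`` when a dict is supplied.
    """
    if matrix.n_features != params.mins.size:
        raise ValueError("column count does not match normalization params")
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    y = (matrix.values - params.mins) / safe
    y[:, params.degenerate] = 0.0
    n_clipped = int(((y < 0) | (y > 1)).sum())
    if clip_log is not None:
        clip_log["n_clipped"] = clip_log.get("n_clipped", 0) + n_clipped
    y = np.clip(y, 0.0, 1.0)
    return FeatureMatrix(y, list(matrix.feature_names), matrix.labels,
                         list(matrix.sample_ids), list(matrix.patient_ids))


def compare_groups_ttest(matrix: FeatureMatrix, feature: str,
                         variant: str = "pooled") -> dict:
    """Two-sample t-test of one feature between nodule and normal groups.

    Returns the t statistic, two-sided p-value, per-class mean +- sd and the
    F value reported as ``t**2`` (an interpretation recorded in the output
    metadata, not asserted as the original computation).
    """
    x = matrix.column(feature)
    pos = x[matrix.labels == 1]
    neg = x[matrix.labels == -1]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 samples in each class")
    equal_var = variant == "pooled"
    t, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return {
        "feature": feature,
        "t": float(t),
        "p": float(p),
        "F": float(t) ** 2,
        "F_definition": "t_squared",
        "nodule_mean": float(pos.mean()),
        "nodule_sd": float(pos.std(ddof=1)),
        "normal_mean": float(neg.mean()),
        "normal_sd": float(neg.std(ddof=1)),
        "variant": variant,
    }


def split_selection_validation(matrix: FeatureMatrix, fraction: float = 0.5,
                               seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random split into selection and validation groups."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    idx = np.arange(matrix.n_samples)
    sel, val = train_test_split(idx, train_size=fraction, random_state=seed,
                                stratify=matrix.labels, shuffle=True)
    sel_m, val_m = matrix.subset_rows(np.sort(sel)), matrix.subset_rows(np.sort(val))
    for part, name in ((sel_m, "selection"), (val_m, "validation")):
        if len(set(part.labels)) < 2:
            raise ValueError(f"{name} split lost a class; use more samples")
    return sel_m, val_m
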