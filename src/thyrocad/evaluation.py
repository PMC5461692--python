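"""Confusion-matrix metrics, ROC/AUC, and report rendering.

The positive class is the nodule.  With N_TP / N_TN the correctly
identified nodule / normal counts and N_FP / N_FN the misidentified ones:

    SEN = N_TP / (N_TP + N_FN)          SPC = N_TN / (N_TN + N_FP)
    PPV = N_TP / (N_TP + N_FP)          NPV = N_TN / (N_TN + N_FN)
    ACC = (N_TP + N_TN) / total

A metric whose denominator is zero is reported as 0 with a flag (the
convention an all-negative classifier produces: SEN 0.000, PPV 0.000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "render_reports",
]


@dataclass
class ConfusionMatrix:
    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_tn", "n_fp", "n_fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


@dataclass
class MetricsReport:
    sen: float
    spc: float
    ppv: float
    npv: float
    acc: float
    auc: float | None = None
    zero_denominator_flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        d = {"ACC": self.acc, "SEN": self.sen, "SPC": self.spc,
             "PPV": self.ppv, "NPV": self.npv}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def confusion_counts(true_labels, predicted_labels) -> ConfusionMatrix:
    """Tally the four counts; labels must be +1 (nodule) / -1 (normal)."""
    yt = np.asarray(true_labels, dtype=int)
    yp = np.asarray(predicted_labels, dtype=int)
    if yt.size != yp.size:
        raise ValueError("label vectors differ in length")
    if yt.size < 1:
        raise ValueError("empty label vectors")
    for arr, name in ((yt, "true"), (yp, "predicted")):
        if not np.all(np.isin(arr, [-1, 1])):
            raise ValueError(f"{name} labels must be +1 or -1")
    return ConfusionMatrix(
        n_tp=int(((yt == 1) & (yp == 1)).sum()),
        n_tn=int(((yt == -1) & (yp == -1)).sum()),
        n_fp=int(((yt == -1) & (yp == 1)).sum()),
        n_fn=int(((yt == 1) & (yp == -1)).sum()),
    )


def _ratio(num: int, den: int, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    flags: set[str] = set()
    return MetricsReport(
        sen=_ratio(cm.n_tp, cm.n_tp + cm.n_fn, "SEN", flags),
        spc=_ratio(cm.n_tn, cm.n_tn + cm.n_fp, "SPC", flags),
        ppv=_ratio(cm.n_tp, cm.n_tp + cm.n_fp, "PPV", flags),
        npv=_ratio(cm.n_tn, cm.n_tn + cm.n_fn, "NPV", flags),
        acc=_ratio(cm.n_tp + cm.n_tn, cm.total, "ACC", flags),
        auc=auc,
        zero_denominator_flags=flags,
    )


def roc_auc(scores, true_labels) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    The AUC equals the normalized Mann-Whitney U statistic, with tied scores
    contributing 1/2.  Returns an array of (fpr, tpr, threshold) rows and
    the scalar AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied thresholds: take cumulative counts at the last of each tie run
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == -1)
    last_of_run = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp, fp = tp[last_of_run], fp[last_of_run]
    thresholds = s_sorted[last_of_run]

    tpr = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))
    thresholds = np.concatenate(([np.inf], thresholds))
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr, thresholds])
    return curve, auc


def _round3(x: float) -> float:
    """Half-up rounding to 3 decimals, matching conventional table rendering."""
    import decimal

    return float(decimal.Decimal(repr(x)).quantize(
        decimal.Decimal("0.001"), rounding=decimal.ROUND_HALF_UP))


METRIC_COLUMNS = ["ACC", "SEN", "SPC", "PPV", "NPV", "AUC"]


def render_reports(results: list[dict], out_dir: str | Path) -> dict[str, Path]:
    """Write per-configuration metric tables and confusion counts as CSV.

    ``results`` rows carry ``name`` (configuration label, e.g. a feature or
    a subset string like "A6, M6, W6"), a ``metrics`` MetricsReport, an
    optional ``selected`` feature list and an optional ``confusion``
    ConfusionMatrix.  Values are rendered at 3 decimals (half-up); full
    precision stays with the caller.
    """
    if not results:
        raise ValueError("nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        met: MetricsReport = res["metrics"]
        row = {"configuration": res["name"]}
        if "selected" in res:
            row["selected_features"] = ", ".join(res["selected"])
        row.update({k: _round3(v) for k, v in met.as_dict().items()})
        rows.append(row)
    paths: dict[str, Path] = {}
    metrics_path = out_dir / "metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False)
    paths["metrics"] = metrics_path

    cm_rows = []
    for res in results:
        cm = res.get("confusion")
        if cm is not None:
            cm_rows.append({"configuration": res["name"], "n_tp": cm.n_tp,
                            "n_fn": cm.n_fn, "n_tn": cm.n_tn, "n_fp": cm.n_fp})
    if cm_rows:
        cm_path = out_dir / "confusion.csv"
        pd.DataFrame(cm_rows).to_csv(cm_path, index=False)
        paths["confusion"] = cm_path

    for res in results:
        if "roc_curve" in res:
            roc_path = out_dir / f"roc_{res['name'].replace(', ', '+').replace(' ', '_')}.csv"
            pd.DataFrame(res["roc_curve"], columns=["fpr", "tpr", "threshold"]
                         ).to_csv(roc_path, index=False)
            paths.setdefault("roc", roc_path)
    return paths
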