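"""End-to-end experiment orchestration: simulate -> extract -> select ->
classify -> evaluate -> report.

The stages mirror the CAD workflow: ROIs (clinical or phantom) are filtered
with the 3x3 bank, six first-order features are computed per filter group,
features are min-max normalized, SFFS picks a subset on a selection split,
and classifiers are scored by leave-one-out cross-validation with all
fitting redone inside each fold.  Every stochastic stage draws from a named
seed recorded in the summary, so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classification import SVMConfig, loocv_evaluate
from .dataset import (FeatureMatrix, GROUP_ORDER, apply_min_max,
                      build_feature_matrix, compare_groups_ttest, fit_min_max,
                      group_columns, split_selection_validation)
from .evaluation import (compute_metrics, confusion_counts, render_reports,
                         roc_auc)
from .features import extract_first_order
from .imaging_io import apply_mask, load_ct_image, load_mask, read_manifest
from .preprocessing import FilterSpec, build_filter_bank
from .selection import knn_loocv_accuracy, sffs_select
from .synthetic_data import PhantomConfig, generate_dataset

logger = logging.getLogger("thyrocad")

__all__ = ["RunConfig", "extract_feature_table", "run_extract", "run_experiment"]

#: Filter kinds in group order 1..4 (wiener, median, average, unfiltered).
DEFAULT_FILTERS = ("wiener", "median", "average", "none")

KIND_TO_TAG = {"wiener": "W6", "median": "M6", "average": "A6", "none": "non-filter"}


@dataclass
class RunConfig:
    manifest: str = ""
    out_dir: str = "thyrocad_out"
    filters: Sequence[str] = DEFAULT_FILTERS
    window: int = 3
    n_bins: int = 256
    range_policy: str = "roi_minmax"
    subsets: Sequence[Sequence[str]] = (("A6", "M6", "W6"),)
    use_sffs: bool = True
    sffs_k: int = 1
    sffs_max_features: int | None = None
    split_fraction: float = 0.5
    classifiers: Sequence[str] = ("svm",)
    cv_grouping: str = "image"
    grid_mode: str = "nested"
    svm_cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def extract_feature_table(samples: Iterable[tuple], filters: Sequence[str] = DEFAULT_FILTERS,
                          window: int = 3, n_bins: int = 256,
                          range_policy: str = "roi_minmax") -> pd.DataFrame:
    """Compute the per-group first-order feature table.

    ``samples`` yields (image, mask, label, sample_id, patient_id).  Output
    columns follow the group-suffix convention (e1..s1 wiener, ... e4..s4
    unfiltered) for whichever filter groups are requested.
    """
    specs = [FilterSpec(kind=kind, window=window) for kind in filters]
    rows = []
    for image, mask, label, sample_id, patient_id in samples:
        row: dict = {"sample_id": sample_id, "patient_id": patient_id, "label": label}
        for filtered in build_filter_bank(image, specs):
            roi = apply_mask(filtered, mask, label=label, patient_id=patient_id)
            fv = extract_first_order(roi, n_bins=n_bins, range_policy=range_policy)
            idx = GROUP_ORDER[filtered.group_tag]
            for name, value in fv.as_dict().items():
                row[f"{name}{idx}"] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = []
    for idx in (1, 2, 3, 4):
        ordered.extend([c for c in df.columns if c.endswith(str(idx))
                        and c not in ("sample_id", "patient_id", "label")])
    return df[["sample_id", "patient_id", "label"] + ordered]


def run_extract(config: RunConfig) -> pd.DataFrame:
    """Extract features for every manifest row; skip and log unreadable ones."""
    manifest = read_manifest(config.manifest)

    def iter_samples():
        for i, row in manifest.iterrows():
            try:
                image = load_ct_image(row["image_path"])
                mask = load_mask(row["mask_path"], image)
            except Exception as exc:  # unreadable sample: log + continue
                logger.warning("skipping row %d (%s): %s", i, row["image_path"], exc)
                continue
            yield image, mask, row["label"], Path(row["image_path"]).stem, row["patient_id"]

    df = extract_feature_table(iter_samples(), filters=config.filters,
                               window=config.window, n_bins=config.n_bins,
                               range_policy=config.range_policy)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "features.csv", index=False)
    return df


def _subset_columns(subset: Sequence[str], available: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for tag in subset:
        if tag not in GROUP_ORDER:
            raise ValueError(f"unknown feature group {tag!r}")
        tag_cols = group_columns(tag)
        missing = [c for c in tag_cols if c not in available]
        if missing:
            raise ValueError(f"feature table lacks columns {missing} for group {tag}")
        cols.extend(tag_cols)
    return cols


def subset_name(subset: Sequence[str]) -> str:
    return ", ".join(subset)


def evaluate_subset(matrix: FeatureMatrix, config: RunConfig,
                    classifier: str = "svm") -> dict:
    """SFFS (optional) on a selection split, then LOOCV on the chosen columns."""
    result: dict = {}
    work = matrix
    if config.use_sffs and matrix.n_features >= 2:
        sel_m, val_m = split_selection_validation(matrix, config.split_fraction,
                                                  seed=config.seed)
        params = fit_min_max(sel_m)
        sel_norm = apply_min_max(sel_m, params)
        sffs = sffs_select(sel_norm, k=config.sffs_k,
                           max_features=config.sffs_max_features)
        val_norm = apply_min_max(val_m, params)
        val_score = knn_loocv_accuracy(val_norm, sffs.selected, k=config.sffs_k)
        result["selected"] = sffs.selected
        result["sffs_criterion"] = sffs.best_criterion
        result["validation_criterion"] = val_score
        work = matrix.select_features(sffs.selected)
    else:
        result["selected"] = list(matrix.feature_names)

    svm_config = SVMConfig(cv_folds=config.svm_cv_folds)
    y_true, y_pred, scores = loocv_evaluate(
        work, classifier=classifier, grouping=config.cv_grouping,
        seed=config.seed, svm_config=svm_config, grid_mode=config.grid_mode)
    cm = confusion_counts(y_true, y_pred)
    curve, auc = roc_auc(scores, y_true)
    result["confusion"] = cm
    result["metrics"] = compute_metrics(cm, auc=auc)
    result["roc_curve"] = curve
    result["classifier"] = classifier
    return result


def run_experiment(feature_df: pd.DataFrame, config: RunConfig) -> dict:
    """Evaluate every configured subset x classifier; render report tables."""
    matrix_all = FeatureMatrix.from_frame(feature_df)
    results = []
    t_tests = []
    for subset in config.subsets:
        cols = _subset_columns(subset, matrix_all.feature_names)
        sub_matrix = matrix_all.select_features(cols)
        for classifier in config.classifiers:
            t0 = time.perf_counter()
            res = evaluate_subset(sub_matrix, config, classifier=classifier)
            res["name"] = (subset_name(subset) if len(config.classifiers) == 1
                           else f"{subset_name(subset)} [{classifier}]")
            res["elapsed_s"] = time.perf_counter() - t0
            logger.info("%s: ACC=%.3f AUC=%.3f (%.1fs)", res["name"],
                        res["metrics"].acc, res["metrics"].auc, res["elapsed_s"])
            results.append(res)

    norm_all = apply_min_max(matrix_all, fit_min_max(matrix_all))
    for feature in matrix_all.feature_names:
        t_tests.append(compare_groups_ttest(norm_all, feature))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = render_reports(results, out_dir)
    pd.DataFrame(t_tests).to_csv(out_dir / "group_comparison.csv", index=False)

    summary = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "results": [
            {
                "name": r["name"],
                "classifier": r["classifier"],
                "selected": r["selected"],
                "metrics": r["metrics"].as_dict(),
                "confusion": {"n_tp": r["confusion"].n_tp, "n_fn": r["confusion"].n_fn,
                              "n_tn": r["confusion"].n_tn, "n_fp": r["confusion"].n_fp},
            }
            for r in results
        ],
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    summary["report_paths"] = {k: str(v) for k, v in paths.items()}
    summary["_results_full"] = results
    summary["_t_tests"] = t_tests
    return summary


def simulate(config: RunConfig, n_normal: int = 150, n_nodule: int = 134,
             phantom: PhantomConfig | None = None) -> pd.DataFrame:
    """Write a phantom cohort + manifest into the configured output directory."""
    template = phantom or PhantomConfig()
    out = Path(config.out_dir) / "phantoms"
    manifest = generate_dataset(template, n_normal, n_nodule, seed=config.seed,
                                out_dir=out)
    return manifest
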