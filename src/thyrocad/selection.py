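"""Sequential floating forward selection (SFFS) with a kNN/LOOCV criterion.

The criterion is leave-one-out accuracy of a k-nearest-neighbour classifier
on the candidate feature subset (Euclidean distance on the already
min-max-normalized columns).  SFFS alternates greedy forward additions with
conditional backward removals: after each addition, any feature whose
removal strictly improves the best criterion recorded for the smaller
subset size is dropped.  Because subset search is sensitive to ties, every
tie rule is fixed:

* distance ties between neighbours -> lower sample index wins;
* vote ties -> negative (normal) class;
* criterion ties between subsets -> smaller subset, then feature order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureMatrix

__all__ = ["SFFSResult", "knn_loocv_accuracy", "sffs_select", "sfs_select"]


@dataclass
class SFFSResult:
    selected: list[str]
    criterion_trace: list[tuple[str, str, float]]  # (step kind, feature, criterion)
    best_criterion: float


def knn_loocv_accuracy(matrix: FeatureMatrix, feature_subset: list[str],
                       k: int = 1) -> float:
    """Leave-one-out accuracy of kNN majority vote on the given columns.

    Each sample is classified by its k nearest neighbours among all *other*
    samples.  Ties: equal distances resolve to the lower sample index; tied
    votes resolve to the negative class.
    """
    if not feature_subset:
        raise ValueError("feature subset is empty")
    n = matrix.n_samples
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples, got k={k}, n={n}")
    x = matrix.select_features(list(feature_subset)).values
    y = matrix.labels

    # pairwise squared distances; self-distance masked out
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(sq, np.inf)
    # stable argsort on distance -> equal distances keep lower index first
    order = np.argsort(sq, axis=1, kind="stable")[:, :k]
    votes = y[order].sum(axis=1)
    pred = np.where(votes > 0, 1, -1)  # tie (votes == 0) -> negative class
    return float((pred == y).mean())


def _better(cand: tuple[float, int, tuple[int, ...]],
            best: tuple[float, int, tuple[int, ...]] | None) -> bool:
    """Criterion tie-break: higher accuracy, then smaller subset, then order."""
    if best is None:
        return True
    c_acc, c_size, c_feats = cand
    b_acc, b_size, b_feats = best
    if c_acc != b_acc:
        return c_acc > b_acc
    if c_size != b_size:
        return c_size < b_size
    return c_feats < b_feats


def sffs_select(matrix: FeatureMatrix, k: int = 1,
                max_features: int | None = None) -> SFFSResult:
    """Classic SFFS over the matrix's columns with the kNN/LOOCV criterion.

    Forward steps add the feature maximizing the criterion; floating
    backward steps remove any feature whose removal strictly improves the
    best criterion recorded for that subset size.  The best subset over all
    visited sizes is returned.
    """
    names = matrix.feature_names
    d = len(names)
    if d < 2:
        raise ValueError("need at least 2 features for subset selection")
    if len(set(matrix.labels)) < 2:
        raise ValueError("both classes must be present")
    if max_features is None or max_features > d:
        max_features = d

    def crit(subset: tuple[int, ...]) -> float:
        return knn_loocv_accuracy(matrix, [names[i] for i in subset], k=k)

    trace: list[tuple[str, str, float]] = []
    best_by_size: dict[int, tuple[float, tuple[int, ...]]] = {}
    current: tuple[int, ...] = ()

    def record(size: int, acc: float, subset: tuple[int, ...]) -> None:
        prev = best_by_size.get(size)
        cand = (acc, size, subset)
        if prev is None or _better(cand, (prev[0], size, prev[1])):
            best_by_size[size] = (acc, subset)

    while len(current) < max_features:
        # forward: best single addition (ties -> feature order)
        remaining = [i for i in range(d) if i not in current]
        fwd_best: tuple[float, tuple[int, ...]] | None = None
        fwd_feat = -1
        for i in remaining:
            subset = tuple(sorted(current + (i,)))
            acc = crit(subset)
            if fwd_best is None or acc > fwd_best[0]:
                fwd_best = (acc, subset)
                fwd_feat = i
        assert fwd_best is not None
        new_size = len(current) + 1
        prev = best_by_size.get(new_size)
        if prev is not None and fwd_best[0] <= prev[0]:
            # no forward step improves on a subset of this size already seen
            break
        current = fwd_best[1]
        record(new_size, fwd_best[0], current)
        trace.append(("add", names[fwd_feat], fwd_best[0]))

        # floating backward removals
        while len(current) > 2:
            back_best: tuple[float, tuple[int, ...]] | None = None
            back_feat = -1
            for i in current:
                subset = tuple(s for s in current if s != i)
                acc = crit(subset)
                if back_best is None or acc > back_best[0]:
                    back_best = (acc, subset)
                    back_feat = i
            assert back_best is not None
            size = len(current) - 1
            prev = best_by_size.get(size)
            if prev is not None and back_best[0] > prev[0]:
                current = back_best[1]
                record(size, back_best[0], current)
                trace.append(("remove", names[back_feat], back_best[0]))
            else:
                break

    overall: tuple[float, int, tuple[int, ...]] | None = None
    for size, (acc, subset) in best_by_size.items():
        cand = (acc, size, subset)
        if _better(cand, overall):
            overall = cand
    assert overall is not None
    acc, _, subset = overall
    return SFFSResult(selected=[names[i] for i in subset],
                      criterion_trace=trace, best_criterion=acc)


def sfs_select(matrix: FeatureMatrix, k: int = 1,
               max_features: int | None = None) -> SFFSResult:
    """Plain sequential forward selection (no floating removals).

    Greedy additions up to ``max_features``; returns the best prefix subset.
    Used as a baseline against which the floating variant is compared.
    """
    names = matrix.feature_names
    d = len(names)
    if max_features is None or max_features > d:
        max_features = d

    def crit(subset: tuple[int, ...]) -> float:
        return knn_loocv_accuracy(matrix, [names[i] for i in subset], k=k)

    trace: list[tuple[str, str, float]] = []
    current: tuple[int, ...] = ()
    best: tuple[float, int, tuple[int, ...]] | None = None
    while len(current) < max_features:
        remaining = [i for i in range(d) if i not in current]
        step_best: tuple[float, tuple[int, ...]] | None = None
        step_feat = -1
        for i in remaining:
            subset = tuple(sorted(current + (i,)))
            acc = crit(subset)
            if step_best is None or acc > step_best[0]:
                step_best = (acc, subset)
                step_feat = i
        assert step_best is not None
        current = step_best[1]
        trace.append(("add", names[step_feat], step_best[0]))
        cand = (step_best[0], len(current), current)
        if _better(cand, best):
            best = cand
    assert best is not None
    acc, _, subset = best
    return SFFSResult(selected=[names[i] for i in subset],
                      criterion_trace=trace, best_criterion=acc)
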