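"""ROC evaluation with the ten-split train/test protocol.

The dataset is randomly halved into training and test sets, stratified by
class (odd class counts send the extra ROI to the training side, e.g.
117 -> 59 train / 58 test), ten times with independent draws.  Every
method is trained on the same training half and scored on the same test
half of each split, which licenses the paired t-test on the per-split AUC
values.  ROC curves are averaged vertically (mean TPR on a fixed FPR
grid) and the reported spread is the standard deviation across splits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from . import classify as _clf
from .classify import (
    AnnModel,
    RuleDecision,
    RuleThresholds,
    ann_scores,
    combined_rule,
    learn_rule_thresholds,
    rule_classify,
    train_ann,
)
from .spectrum import build_feature_vector

#: Enhancement branches feeding each evaluable method.
METHOD_BRANCHES = {
    "trend_only": ("trend_only",),
    "window": ("window",),
    "tophat": ("tophat",),
    "glcom": ("glcom",),
    "combined": ("window", "tophat", "glcom"),
}

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class SplitPlan:
    """Stratified random halvings: per-split train/test id lists."""

    train_ids: List[List[str]]
    test_ids: List[List[str]]
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.train_ids)


@dataclass
class RocResult:
    """Split-wise AUCs, their mean and SD, and the vertically averaged
    ROC curve on :data:`FPR_GRID`."""

    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    mean_tpr: np.ndarray

    @classmethod
    def from_aucs(cls, aucs, curves) -> "RocResult":
        aucs = np.asarray(aucs, dtype=float)
        return cls(
            aucs=aucs,
            mean_auc=float(aucs.mean()),
            sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
            mean_tpr=average_roc(curves),
        )


def _ids_and_labels(rois) -> Tuple[List[str], np.ndarray]:
    ids = [r.id for r in rois]
    labels = np.array([r.label == "abnormal" for r in rois])
    return ids, labels


def make_splits(rois, n_splits: int = 10, seed: int = 0) -> SplitPlan:
    """Build ``n_splits`` independent class-stratified random halvings.

    Within each class, ceil(n/2) ids go to training and floor(n/2) to
    test, so class counts per side differ by at most one from an even
    split and train/test are disjoint by construction.
    """
    ids, labels = _ids_and_labels(rois)
    ids = np.asarray(ids)
    for cls in (True, False):
        if (labels == cls).sum() < 2:
            raise ValueError("each class needs at least 2 ROIs to split")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for _ in range(n_splits):
        tr: List[str] = []
        te: List[str] = []
        for cls in (False, True):
            cls_ids = ids[labels == cls]
            perm = rng.permutation(len(cls_ids))
            n_train = math.ceil(len(cls_ids) / 2)
            tr.extend(cls_ids[perm[:n_train]])
            te.extend(cls_ids[perm[n_train:]])
        train_ids.append(tr)
        test_ids.append(te)
    return SplitPlan(train_ids=train_ids, test_ids=test_ids, seed=seed)


def roc_auc(scores, labels) -> float:
    """Empirical AUC (trapezoidal over the ROC steps), identical to the
    Mann-Whitney U statistic normalized by n+ * n-, with half credit for
    ties."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == "abnormal"
    labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def average_roc(curves: Sequence[Tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Vertical ROC averaging: mean TPR at each point of the fixed FPR
    grid, with each curve linearly interpolated onto the grid."""
    if not curves:
        raise ValueError("average_roc needs at least one curve")
    tprs = []
    for fpr, tpr in curves:
        tprs.append(np.interp(FPR_GRID, np.asarray(fpr), np.asarray(tpr)))
    return np.mean(tprs, axis=0)


def paired_t_test(auc_a, auc_b) -> Tuple[float, float]:
    """Two-tailed paired t-test on matched AUC lists.

    Identical lists give (0, 1).  Zero-variance but nonzero-mean
    differences are degenerate: t is signed infinity and p is reported as
    0.0 with a warning.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t_test needs two equal-length lists, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero-mean differences: p below machine floor",
                      RuntimeWarning, stacklevel=2)
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# method fitting / scoring


@dataclass
class FittedMethod:
    """One trained method: per-branch rule thresholds plus a network on the
    concatenated branch features."""

    method: str
    thresholds: Dict[str, RuleThresholds]
    model: AnnModel


def _stack(features: Dict[str, "np.ndarray"], ids: Sequence[str],
           branches: Sequence[str]) -> np.ndarray:
    return np.array(
        [np.concatenate([features[i].branch_features[b] for b in branches]) for i in ids]
    )


def fit_method(method: str, features, ids, labels, *, seed: int = 0,
               ann_params: Optional[dict] = None) -> FittedMethod:
    """Train rule thresholds and the network of one method on a training set."""
    branches = METHOD_BRANCHES[method]
    ann_params = dict(ann_params or {})
    thresholds = {
        b: learn_rule_thresholds(
            np.array([features[i].branch_features[b] for i in ids]), labels
        )
        for b in branches
    }
    X = _stack(features, ids, branches)
    model = train_ann(X, labels, seed=seed, **ann_params)
    return FittedMethod(method=method, thresholds=thresholds, model=model)


def score_method(fitted: FittedMethod, features, ids) -> np.ndarray:
    """Rule-plus-network scores for a list of ROI ids."""
    branches = METHOD_BRANCHES[fitted.method]
    X = _stack(features, ids, branches)
    net = ann_scores(fitted.model, X)
    out = np.empty(len(ids))
    for j, roi_id in enumerate(ids):
        decisions = [
            rule_classify(features[roi_id].branch_features[b], fitted.thresholds[b])
            for b in branches
        ]
        decision = combined_rule(decisions) if len(decisions) == 3 else decisions[0]
        out[j] = _clf.fuse_score(decision, net[j]).value
    return out


@dataclass
class ExperimentResult:
    """Per-method ROC summaries and pairwise paired-t p-values."""

    roc: Dict[str, RocResult]
    pairwise: pd.DataFrame
    plan: SplitPlan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": list(self.roc),
                "mean_auc": [r.mean_auc for r in self.roc.values()],
                "sd_auc": [r.sd_auc for r in self.roc.values()],
            }
        )


def run_experiment(rois, methods=("trend_only", "combined"), n_splits: int = 10,
                   seed: int = 0, *, branch_params: Optional[dict] = None,
                   ann_params: Optional[dict] = None,
                   features: Optional[dict] = None) -> ExperimentResult:
    """Train and score every method on the same stratified splits.

    Features are extracted once per ROI; rule thresholds and network
    weights are re-learned per split from the training half only.  Returns
    mean +/- SD AUC per method, the averaged ROC curves, and a two-tailed
    paired t-test p-value for each method pair.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHOD_BRANCHES)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    labels_by_id = {r.id: r.label == "abnormal" for r in rois}
    if features is None:
        needed = sorted({b for m in methods for b in METHOD_BRANCHES[m]})
        features = {
            r.id: build_feature_vector(r, branches=needed, **(branch_params or {}))
            for r in rois
        }
    plan = make_splits(rois, n_splits=n_splits, seed=seed)
    aucs: Dict[str, List[float]] = {m: [] for m in methods}
    curves: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {m: [] for m in methods}
    for si in range(plan.n_splits):
        tr_ids, te_ids = plan.train_ids[si], plan.test_ids[si]
        y_tr = np.array([labels_by_id[i] for i in tr_ids])
        y_te = np.array([labels_by_id[i] for i in te_ids])
        for mi, method in enumerate(methods):
            mseed = int(
                np.random.SeedSequence([seed, si, mi]).generate_state(1)[0] % (2**31)
            )
            fitted = fit_method(method, features, tr_ids, y_tr, seed=mseed,
                                ann_params=ann_params)
            scores = score_method(fitted, features, te_ids)
            aucs[method].append(roc_auc(scores, y_te))
            fpr, tpr, _ = roc_curve(y_te, scores)
            curves[method].append((fpr, tpr))
    roc = {m: RocResult.from_aucs(aucs[m], curves[m]) for m in methods}
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            if n_splits >= 2:
                t, p = paired_t_test(aucs[ma], aucs[mb])
            else:
                t, p = np.nan, np.nan
            rows.append({"method_a": ma, "method_b": mb, "t": t, "p": p})
    pairwise = pd.DataFrame(rows, columns=["method_a", "method_b", "t", "p"])
    return ExperimentResult(roc=roc, pairwise=pairwise, plan=plan)
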