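"""Rule-based pre-classification, three-layer perceptron, and their fusion.

The rule-based stage looks only at the normalized PS features at radial
bins 1 and 2 of the main axis -- for a 32-pixel ROI at 0.175 mm/pixel these
are 0.179 and 0.357 cycles/mm, the spatial frequencies of nodular
patterns.  On the training set it records, per bin, the highest value seen
in any normal ROI and the lowest seen in any abnormal ROI.  A test ROI
whose value at either bin exceeds the normal maximum is "obviously"
abnormal; one whose values at both bins fall below the abnormal minimum is
"obviously" normal; everything else is left to the network.

The network is a fully connected three-layer perceptron with logistic
sigmoid units throughout, trained by full-batch gradient descent with
momentum on squared error against targets 0.1 (normal) and 0.9 (abnormal).
Architectures follow the input width: 32-17-1 for the image-domain
branches, 64-33-1 for the co-occurrence branch, 128-65-1 for the combined
feature vector.

Fusion: per-branch rule decisions are merged by logical OR (any abnormal
vote wins, then any normal vote); rule-forced decisions score 1.0 / 0.0 so
ROC ranks them extremal, and undecided ROIs receive the network output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Sequence

import numpy as np

RULE_BINS = (0, 1)  # feature indices of radial bins 1 and 2 on the main axis


class RuleDecision(Enum):
    OBVIOUSLY_ABNORMAL = "obviously_abnormal"
    OBVIOUSLY_NORMAL = "obviously_normal"
    UNDECIDED = "undecided"


@dataclass
class RuleThresholds:
    """Per-bin decision bounds learned from training data only.

    ``max_normal[i]`` / ``min_abnormal[i]`` are the extreme training values
    at main-axis radial bin ``i + 1``.  Overlapping classes are allowed
    (``max_normal > min_abnormal``); the rules then rarely fire.
    """

    max_normal: np.ndarray
    min_abnormal: np.ndarray


@dataclass
class CadScore:
    """Final abnormality score in [0, 1] with its provenance."""

    value: float
    provenance: str  # "rule_abnormal", "rule_normal" or "ann"


def _as_label_array(labels) -> np.ndarray:
    """Coerce labels to a boolean abnormal mask."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        return labels == "abnormal"
    return labels.astype(bool)


def learn_rule_thresholds(features, labels) -> RuleThresholds:
    """Learn per-bin extreme values from a two-class training set.

    ``features`` is an (n, k>=2) array of branch feature vectors whose
    first two entries are the main-axis values at radial bins 1 and 2.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    abnormal = _as_label_array(labels)
    if not abnormal.any() or abnormal.all():
        raise ValueError("rule thresholds need both classes in the training set")
    bins = X[:, list(RULE_BINS)]
    return RuleThresholds(
        max_normal=bins[~abnormal].max(axis=0),
        min_abnormal=bins[abnormal].min(axis=0),
    )


def rule_classify(feature, thresholds: RuleThresholds) -> RuleDecision:
    """Classify one feature vector against learned thresholds.

    Abnormal if EITHER bin exceeds its normal maximum; normal only if BOTH
    bins fall below their abnormal minimum; otherwise undecided.
    """
    v = np.asarray(feature, dtype=float)[list(RULE_BINS)]
    if np.any(v > thresholds.max_normal):
        return RuleDecision.OBVIOUSLY_ABNORMAL
    if np.all(v < thresholds.min_abnormal):
        return RuleDecision.OBVIOUSLY_NORMAL
    return RuleDecision.UNDECIDED


@dataclass
class AnnModel:
    """Three-layer perceptron: input -> sigmoid hidden -> sigmoid output."""

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    hyper: dict = field(default_factory=dict)

    @property
    def arch(self):
        return (self.w1.shape[0], self.w1.shape[1], 1)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def default_hidden(n_in: int) -> int:
    """Hidden-layer width convention: half the input width plus one
    (32 -> 17, 64 -> 33, 128 -> 65)."""
    return n_in // 2 + 1


def train_ann(features, labels, hidden: int | None = None, *,
              learning_rate: float = 0.05, momentum: float = 0.9,
              epochs: int = 500, seed: int = 0) -> AnnModel:
    """Train the perceptron by full-batch gradient descent with momentum.

    Targets are 0.1 for normal and 0.9 for abnormal patterns; weights are
    initialized uniform(-0.5, 0.5) from ``seed``, so training is
    deterministic for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    abnormal = _as_label_array(labels)
    if len(abnormal) != X.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not abnormal.any() or abnormal.all():
        raise ValueError("training needs both classes")
    t = np.where(abnormal, 0.9, 0.1)
    n, d = X.shape
    h = default_hidden(d) if hidden is None else int(hidden)
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.5, 0.5, size=(d, h))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=h)
    b2 = float(rng.uniform(-0.5, 0.5))
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0
    final_error = np.nan
    for _ in range(epochs):
        H = _sigmoid(X @ w1 + b1)
        o = _sigmoid(H @ w2 + b2)
        err = o - t
        final_error = float(np.mean(err**2))
        do = err * o * (1.0 - o) * (2.0 / n)
        g_w2 = H.T @ do
        g_b2 = float(do.sum())
        dh = np.outer(do, w2) * H * (1.0 - H)
        g_w1 = X.T @ dh
        g_b1 = dh.sum(axis=0)
        v_w1 = momentum * v_w1 - learning_rate * g_w1
        v_b1 = momentum * v_b1 - learning_rate * g_b1
        v_w2 = momentum * v_w2 - learning_rate * g_w2
        v_b2 = momentum * v_b2 - learning_rate * g_b2
        w1 += v_w1
        b1 += v_b1
        w2 += v_w2
        b2 += v_b2
    return AnnModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        hyper={
            "learning_rate": learning_rate, "momentum": momentum,
            "epochs": epochs, "seed": seed, "final_error": final_error,
        },
    )


def ann_score(model: AnnModel, feature) -> float:
    """Forward pass for a single feature vector; output in (0, 1)."""
    x = np.asarray(feature, dtype=float)
    if x.shape != (model.w1.shape[0],):
        raise ValueError(
            f"feature length {x.shape} does not match model input {model.w1.shape[0]}"
        )
    hid = _sigmoid(x @ model.w1 + model.b1)
    return float(_sigmoid(hid @ model.w2 + model.b2))


def ann_scores(model: AnnModel, features) -> np.ndarray:
    """Vectorized forward pass for an (n, d) feature matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.w1.shape[0]:
        raise ValueError("feature width does not match model input size")
    hid = _sigmoid(X @ model.w1 + model.b1)
    return _sigmoid(hid @ model.w2 + model.b2)


def combined_rule(decisions: Sequence[RuleDecision]) -> RuleDecision:
    """Logical-OR fusion of the three per-branch rule decisions.

    Any abnormal vote forces obviously-abnormal (abnormal precedence keeps
    false negatives down); otherwise any normal vote forces
    obviously-normal; otherwise undecided.
    """
    decisions = list(decisions)
    if len(decisions) != 3:
        raise ValueError("combined_rule expects exactly three branch decisions")
    if RuleDecision.OBVIOUSLY_ABNORMAL in decisions:
        return RuleDecision.OBVIOUSLY_ABNORMAL
    if RuleDecision.OBVIOUSLY_NORMAL in decisions:
        return RuleDecision.OBVIOUSLY_NORMAL
    return RuleDecision.UNDECIDED


def fuse_score(decision: RuleDecision, ann_output: float) -> CadScore:
    """Map a rule decision plus network output to the final score."""
    if decision is RuleDecision.OBVIOUSLY_ABNORMAL:
        return CadScore(1.0, "rule_abnormal")
    if decision is RuleDecision.OBVIOUSLY_NORMAL:
        return CadScore(0.0, "rule_normal")
    return CadScore(float(ann_output), "ann")


def cad_score(branch_features: Dict[str, np.ndarray],
              thresholds: Dict[str, RuleThresholds],
              combined_model: AnnModel) -> CadScore:
    """Score one ROI with the combined rule-based plus network method.

    ``branch_features`` must contain the window, tophat and glcom vectors;
    the rule decisions of the three branches are OR-fused and, if
    undecided, the 128-input network scores the concatenated vector.
    """
    order = ("window", "tophat", "glcom")
    decisions = [rule_classify(branch_features[b], thresholds[b]) for b in order]
    decision = combined_rule(decisions)
    if decision is RuleDecision.UNDECIDED:
        combined = np.concatenate([branch_features[b] for b in order])
        return fuse_score(decision, ann_score(combined_model, combined))
    return fuse_score(decision, 0.5)
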