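"""Rule-based classifier, perceptron, and fusion logic."""

import itertools

import numpy as np
import pytest

import pneumotex as px
from pneumotex.classify import (
    RuleDecision,
    ann_scores,
    default_hidden,
    fuse_score,
)

from _oracles import ann_forward, u_statistic_auc

A, N, U = (
    RuleDecision.OBVIOUSLY_ABNORMAL,
    RuleDecision.OBVIOUSLY_NORMAL,
    RuleDecision.UNDECIDED,
)


def _features(bin1, bin2):
    """Feature rows with controlled values at the two rule bins."""
    return np.column_stack([bin1, bin2, np.zeros_like(np.asarray(bin1, dtype=float))])


class TestRuleThresholds:
    def test_extreme_values_recorded(self):
        X = _features([0.1, 0.2, 0.5, 0.9], [0.3, 0.1, 0.6, 0.8])
        y = [False, False, True, True]
        th = px.learn_rule_thresholds(X, y)
        assert th.max_normal[0] == pytest.approx(0.2)
        assert th.min_abnormal[0] == pytest.approx(0.5)
        assert th.max_normal[1] == pytest.approx(0.3)
        assert th.min_abnormal[1] == pytest.approx(0.6)

    def test_overlapping_classes_allowed(self):
        X = _features([0.8, 0.3], [0.8, 0.3])
        th = px.learn_rule_thresholds(X, [False, True])
        assert th.max_normal[0] > th.min_abnormal[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            px.learn_rule_thresholds(_features([0.1, 0.2], [0.1, 0.2]), [False, False])

    def test_thresholds_ignore_test_data(self, rng):
        train_X = _features(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        train_y = np.arange(20) % 2 == 0
        th1 = px.learn_rule_thresholds(train_X, train_y)
        # perturbing a disjoint "test set" cannot change learned thresholds
        _ = _features(rng.uniform(5, 9, 20), rng.uniform(5, 9, 20))
        th2 = px.learn_rule_thresholds(train_X, train_y)
        assert np.array_equal(th1.max_normal, th2.max_normal)
        assert np.array_equal(th1.min_abnormal, th2.min_abnormal)


class TestRuleClassify:
    @pytest.fixture
    def thresholds(self):
        # overlapping classes: max_normal = (0.6, 0.5), min_abnormal = (0.4, 0.3)
        return px.learn_rule_thresholds(
            _features([0.1, 0.6, 0.4, 0.9], [0.1, 0.5, 0.3, 0.8]),
            [False, False, True, True],
        )

    def test_above_max_normal_is_abnormal(self, thresholds):
        assert px.rule_classify([0.7, 0.0, 0.0], thresholds) is A

    def test_below_min_abnormal_on_both_bins_is_normal(self, thresholds):
        assert px.rule_classify([0.35, 0.25, 0.0], thresholds) is N

    def test_between_bounds_is_undecided(self, thresholds):
        assert px.rule_classify([0.5, 0.4, 0.0], thresholds) is U

    def test_training_set_never_cross_labelled(self, rng):
        """By construction of max/min, no training normal is called
        obviously abnormal and no training abnormal obviously normal."""
        for _ in range(20):
            X = _features(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
            y = rng.uniform(size=30) < 0.5
            if y.all() or not y.any():
                continue
            th = px.learn_rule_thresholds(X, y)
            for xi, yi in zip(X, y):
                d = px.rule_classify(xi, th)
                if yi:
                    assert d is not N
                else:
                    assert d is not A


class TestAnn:
    def test_linearly_separable_training_reaches_perfect_auc(self, rng):
        X = np.vstack(
            [rng.normal(0.2, 0.05, (100, 2)), rng.normal(0.8, 0.05, (100, 2))]
        )
        y = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        model = px.train_ann(X, y, hidden=3, epochs=200, seed=1)
        assert u_statistic_auc(ann_scores(model, X), y) == 1.0

    def test_fixed_seed_reproducibility(self, rng):
        X = rng.uniform(0, 1, (30, 8))
        y = np.arange(30) % 2 == 0
        m1 = px.train_ann(X, y, epochs=50, seed=3)
        m2 = px.train_ann(X, y, epochs=50, seed=3)
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert m1.b2 == m2.b2

    def test_default_hidden_layer_widths(self):
        assert default_hidden(32) == 17
        assert default_hidden(64) == 33
        assert default_hidden(128) == 65

    def test_scores_bounded(self, rng):
        X = rng.uniform(0, 1, (20, 4))
        y = np.arange(20) % 2 == 0
        model = px.train_ann(X, y, epochs=20, seed=0)
        s = ann_scores(model, rng.normal(0, 100, (50, 4)))
        assert np.all((s > 0) & (s < 1))

    def test_forward_pass_matches_matrix_free_oracle(self, rng):
        X = rng.uniform(0, 1, (12, 6))
        y = np.arange(12) % 2 == 0
        model = px.train_ann(X, y, epochs=30, seed=7)
        x = rng.uniform(0, 1, 6)
        expected = ann_forward(model.w1, model.b1, model.w2, model.b2, x)
        assert px.ann_score(model, x) == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_model_outputs_sigmoid_bias(self):
        model = px.AnnModel(
            w1=np.zeros((4, 3)), b1=np.zeros(3), w2=np.zeros(3), b2=0.7
        )
        assert px.ann_score(model, np.ones(4)) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.7))
        )

    def test_monotone_along_positive_weight_path(self):
        model = px.AnnModel(
            w1=np.abs(np.random.default_rng(0).normal(size=(4, 3))),
            b1=np.zeros(3),
            w2=np.array([0.5, 1.0, 0.2]),
            b2=0.0,
        )
        x = np.array([0.1, 0.2, 0.3, 0.4])
        scores = [
            px.ann_score(model, x + np.array([delta, 0, 0, 0]))
            for delta in np.linspace(0, 2, 9)
        ]
        assert np.all(np.diff(scores) >= -1e-15)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.uniform(0, 1, (10, 4))
        y = np.arange(10) % 2 == 0
        model = px.train_ann(X, y, epochs=5, seed=0)
        with pytest.raises(ValueError):
            px.ann_score(model, np.zeros(7))
        with pytest.raises(ValueError):
            px.train_ann(X, y[:-1], epochs=5)


class TestCombinedRule:
    def test_or_logic_truth_table(self):
        for triple in itertools.product([A, N, U], repeat=3):
            out = px.combined_rule(triple)
            if A in triple:
                assert out is A
            elif N in triple:
                assert out is N
            else:
                assert out is U

    def test_requires_three_decisions(self):
        with pytest.raises(ValueError):
            px.combined_rule([A, U])


class TestCadScore:
    @pytest.fixture
    def setup(self, small_features, small_labels):
        ids = list(small_features)
        y = np.array([small_labels[i] for i in ids])
        thresholds = {
            b: px.learn_rule_thresholds(
                np.array([small_features[i].branch_features[b] for i in ids]), y
            )
            for b in ("window", "tophat", "glcom")
        }
        X = np.array([small_features[i].combined for i in ids])
        model = px.train_ann(X, y, epochs=50, seed=0)
        return ids, thresholds, model

    def test_rule_forced_scores_are_extremal(self, setup, small_features):
        ids, thresholds, model = setup
        for i in ids:
            bf = small_features[i].branch_features
            decisions = [
                px.rule_classify(bf[b], thresholds[b])
                for b in ("window", "tophat", "glcom")
            ]
            sc = px.cad_score(bf, thresholds, model)
            fused = px.combined_rule(decisions)
            if fused is A:
                assert sc.value == 1.0 and sc.provenance == "rule_abnormal"
            elif fused is N:
                assert sc.value == 0.0 and sc.provenance == "rule_normal"
            else:
                assert sc.value == pytest.approx(
                    px.ann_score(model, small_features[i].combined)
                )
                assert sc.provenance == "ann"

    def test_fuse_contract(self):
        assert fuse_score(A, 0.3).value == 1.0
        assert fuse_score(N, 0.3).value == 0.0
        assert fuse_score(U, 0.3).value == pytest.approx(0.3)
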