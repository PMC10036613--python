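"""Splitting, balancing, classifiers, metrics and confidence analysis."""

import numpy as np
import pytest

from gazestrat.features import BASELINE_COLUMNS, features_frame
from gazestrat.games import StrategyLabel
from gazestrat.models import (
    CT1,
    CT2,
    balance_binary,
    compute_metrics,
    confidence_scores,
    correlate_confidence,
    evaluate,
    images_to_vectors,
    split_participants,
    train_logit,
    train_svm_image,
)


class TestSplit:
    def test_largest_remainder_sizes_for_243_participants(self):
        ids = [f"P{i}" for i in range(243)]
        split = split_participants(ids, (0.7, 0.2, 0.1), seed=1)
        sizes = {s: len(split.ids(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 170, "val": 49, "test": 24}

    def test_partition_is_exact_and_disjoint(self):
        ids = [f"P{i}" for i in range(57)]
        split = split_participants(ids, seed=3)
        groups = [set(split.ids(s)) for s in ("train", "val", "test")]
        assert set().union(*groups) == set(ids)
        assert sum(len(g) for g in groups) == len(ids)

    def test_same_seed_reproduces_assignment(self):
        ids = [f"P{i}" for i in range(40)]
        assert split_participants(ids, seed=9) == split_participants(ids, seed=9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_participants(list("abcdef"), (0.5, 0.2, 0.2), seed=0)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            split_participants(["a", "b"], seed=0)


class TestBalance:
    def test_removes_exactly_the_majority_excess(self):
        records = [("pos", i) for i in range(60)] + [("neg", i) for i in range(45)]
        out = balance_binary(records, key=lambda r: r[0] == "pos", seed=0)
        assert len(out) == 90
        assert sum(r[0] == "pos" for r in out) == 45

    def test_already_balanced_is_unchanged(self):
        records = [("pos", i) for i in range(10)] + [("neg", i) for i in range(10)]
        assert balance_binary(records, key=lambda r: r[0] == "pos", seed=0) == records

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balance_binary([("pos", 1)], key=lambda r: True, seed=0)

    def test_output_is_subset_preserving_order(self):
        records = list(range(30))
        out = balance_binary(records, key=lambda r: r < 20, seed=5)
        assert out == sorted(out) and set(out) <= set(records)


class TestMetrics:
    def test_hand_computed_binary_case(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0], task=CT1)
        assert m.accuracy == 0.75
        assert m.confusion.tolist() == [[2, 0], [1, 1]]
        assert np.trace(m.confusion) / m.n == m.accuracy

    def test_perfectly_ranked_scores_give_unit_auc(self):
        m = compute_metrics([0, 0, 1, 1], [0, 0, 1, 1],
                            scores=[0.1, 0.2, 0.8, 0.9], task=CT1)
        assert m.auc == 1.0 and m.f1 == 1.0

    def test_diagonal_three_class_confusion(self):
        y = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        m = compute_metrics(y, y, task=CT2)
        assert m.accuracy == 1.0 and m.f1 == 1.0
        assert np.array_equal(m.confusion, 5 * np.eye(3, dtype=int))

    def test_weighted_auc_reduces_to_macro_when_balanced(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 30)
        scores = rng.dirichlet(np.ones(3), size=90)
        from sklearn.metrics import roc_auc_score

        weighted = compute_metrics(y, scores.argmax(1), scores=scores, task=CT2).auc
        macro = roc_auc_score(y, scores, multi_class="ovr", average="macro")
        assert weighted == pytest.approx(macro)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], task=CT1)


class TestLogit:
    def test_separable_features_classified_perfectly(self, rng):
        X = np.vstack([rng.uniform(0.6, 0.9, (40, 1)), rng.uniform(0.1, 0.4, (40, 1))])
        X = np.hstack([X, rng.uniform(0, 1, (80, 2))])
        y = np.array([1] * 40 + [0] * 40)
        with pytest.warns(UserWarning, match="separation"):
            model = train_logit(X, y, task=CT1)
        assert (model.predict(X) == y).mean() == 1.0

    def test_identical_features_predict_majority_class(self):
        X = np.ones((30, 3))
        y = np.array([1] * 20 + [0] * 10)
        model = train_logit(X, y, task=CT1)
        assert (model.predict(X) == 1).all()

    def test_counterpart_transitions_drive_equilibrium_coefficient(self, layout, small_cohort):
        """On default synthetic data the equilibrium logit loads positively
        on the proportion of transitions among the counterpart's payoffs."""
        df = features_frame(small_cohort, layout)
        y = (df["label"] == "Equilibrium").astype(int).to_numpy()
        model = train_logit(df[list(BASELINE_COLUMNS)].to_numpy(), y, task=CT1)
        coef = dict(zip(BASELINE_COLUMNS, model.coef_[0]))
        assert coef["prop_trans_other"] > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_logit(np.ones((5, 3)), np.ones(5), task=CT1)


def synthetic_shape_images(rng, n_per_class=25, size=64):
    """Two linearly separable classes: bright top-left vs bottom-right block."""
    imgs, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = np.zeros((size, size, 3), dtype=np.uint8)
            block = rng.integers(150, 255, size=(20, 20, 3), dtype=np.uint8).astype(np.uint8)
            if cls == 0:
                img[5:25, 5:25] = block
            else:
                img[-25:-5, -25:-5] = block
            imgs.append(img)
            labels.append(cls)
    return np.stack(imgs), np.array(labels)


class TestSvmImage:
    def test_separable_classes_fit_perfectly(self, rng):
        imgs, y = synthetic_shape_images(rng)
        model = train_svm_image(imgs, y, task=CT1, seed=0)
        m = evaluate(model, imgs, y, task=CT1, vectorize_images=True)
        assert m.accuracy == 1.0

    def test_grid_search_is_deterministic_per_seed(self, rng):
        imgs, y = synthetic_shape_images(rng, n_per_class=15)
        grid = {"C": [1.0, 10.0], "gamma": [1e-4, 1e-3]}
        a = train_svm_image(imgs, y, cv_config=grid, seed=4)
        b = train_svm_image(imgs, y, cv_config=grid, seed=4)
        assert a._cv_results == b._cv_results
        assert a.C == b.C and a.gamma == b.gamma

    def test_misaligned_labels_rejected(self, rng):
        imgs, y = synthetic_shape_images(rng, n_per_class=5)
        with pytest.raises(ValueError):
            train_svm_image(imgs, y[:-1], task=CT1)

    def test_vectorisation_scales_to_unit_interval(self, rng):
        imgs, _ = synthetic_shape_images(rng, n_per_class=3)
        X = images_to_vectors(imgs)
        assert X.shape == (6, 64 * 64 * 3)
        assert X.min() >= 0.0 and X.max() <= 1.0


class TestConfidence:
    class Dummy:
        classes_ = np.array([0, 1])

        def predict_proba(self, X):
            return np.asarray(X)

    def test_confidence_is_max_class_probability(self):
        conf = confidence_scores(self.Dummy(), [[0.9, 0.1], [0.4, 0.6]])
        assert conf.tolist() == [0.9, 0.6]

    def test_uniform_probabilities_floor(self):
        conf = confidence_scores(self.Dummy(), [[0.5, 0.5]])
        assert conf[0] == 0.5

    def test_probability_free_classifier_rejected(self):
        with pytest.raises(TypeError):
            confidence_scores(object(), [[1.0]])

    def test_confidences_bounded_by_class_count(self, rng):
        probs = rng.dirichlet(np.ones(3), size=50)
        conf = np.asarray(probs).max(axis=1)
        assert np.all(conf >= 1 / 3) and np.all(conf <= 1.0)


class TestCorrelation:
    def test_affine_relation_gives_unit_correlation(self, rng):
        x = rng.uniform(size=50)
        r, p = correlate_confidence(2 * x + 1, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_confidence(np.ones(10), np.arange(10.0))

    def test_independent_vectors_are_nearly_uncorrelated(self, rng):
        r, _ = correlate_confidence(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            correlate_confidence([1.0, 2.0], [1.0, 2.0])
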