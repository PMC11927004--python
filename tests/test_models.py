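"""Cascade training/prediction and the LDA comparators."""

import numpy as np
import pytest

from cwcst.features import FrameDataset
from cwcst.models import (
    LdaModel,
    TrainConfig,
    predict,
    predict_frames,
    predict_lda,
    train_cascade,
    train_lda,
)


def _synthetic_frames(rng, n_per_class=60, classes=("M1", "M2", "M10"),
                      shape=(8, 24)):
    """Linearly separable image datasets: one bright patch per class."""
    images, labels = [], []
    for ci, g in enumerate(classes):
        base = np.zeros(shape, dtype=np.float32)
        if g != "M10":  # rest stays dark
            base[2:6, 4 * ci + 2: 4 * ci + 6] = 3.0
        block = base[None] + 0.3 * rng.standard_normal(
            (n_per_class,) + shape).astype(np.float32)
        images.append(block)
        labels += [g] * n_per_class
    images = np.concatenate(images)
    labels = np.asarray(labels, dtype=object)
    times = np.arange(len(labels), dtype=float)
    perm = rng.permutation(len(labels))
    return FrameDataset(images[perm], labels[perm], times, "cwcst_rate")


class TestCascade:
    def _train(self, rng, seed=0, epochs=30):
        ds = _synthetic_frames(rng)
        cfg = TrainConfig(epochs=epochs, batch=64, val_fraction=0.2, seed=seed)
        return ds, train_cascade(ds, ds, cfg)

    def test_separable_classes_reach_perfect_validation(self, rng):
        ds, model = self._train(rng)
        assert model.history["rest"][-1][2] == 1.0
        assert model.history["gesture"][-1][2] == 1.0
        pred = predict_frames(model, ds.images, ds.images)
        assert np.mean(pred == ds.labels) > 0.95

    def test_same_seed_gives_identical_weights(self, rng):
        ds = _synthetic_frames(rng)
        cfg = TrainConfig(epochs=3, batch=64, seed=9)
        m1 = train_cascade(ds, ds, cfg)
        m2 = train_cascade(ds, ds, cfg)
        for p1, p2 in zip(m1.gesture_net.params(), m2.gesture_net.params()):
            assert np.array_equal(p1.value, p2.value)

    def test_missing_rest_class_raises(self, rng):
        ds = _synthetic_frames(rng, classes=("M1", "M2"))
        with pytest.raises(ValueError, match="M10"):
            train_cascade(ds, ds, TrainConfig(epochs=1, batch=32))

    def test_requested_class_absent_raises_by_name(self, rng):
        ds = _synthetic_frames(rng)
        with pytest.raises(ValueError, match="M7"):
            train_cascade(ds, ds, TrainConfig(epochs=1, batch=32),
                          gesture_classes=["M1", "M2", "M7"])

    def test_predictions_live_in_gesture_set(self, rng):
        ds, model = self._train(rng, epochs=3)
        pred = predict_frames(model, ds.images, ds.images)
        allowed = set(model.gesture_classes) | {model.rest_id}
        assert set(pred.tolist()) <= allowed

    def test_single_frame_prediction_and_shape_check(self, rng):
        ds, model = self._train(rng, epochs=3)
        out = predict(model, ds.images[0], ds.images[0])
        assert out in set(model.gesture_classes) | {model.rest_id}
        with pytest.raises(ValueError):
            predict(model, ds.images[0].ravel(), ds.images[0].ravel())

    def test_rest_only_on_rest_net_vote(self, rng):
        # frames the rest net calls non-rest must get a gesture label
        ds, model = self._train(rng, epochs=3)
        from cwcst.models import predict_log_proba
        rest_votes = np.argmax(
            predict_log_proba(model.rest_net, ds.images), axis=1) == 1
        pred = predict_frames(model, ds.images, ds.images)
        assert np.all((pred == "M10") == rest_votes)


class TestLda:
    def test_two_class_boundary_is_perpendicular_bisector(self, rng):
        X = np.concatenate([rng.standard_normal((200, 2)),
                            rng.standard_normal((200, 2)) + 10.0])
        y = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        model = train_lda(X, y)
        held = np.concatenate([rng.standard_normal((50, 2)),
                               rng.standard_normal((50, 2)) + 10.0])
        pred = predict_lda(model, held)
        assert np.mean(pred == np.array(["A"] * 50 + ["B"] * 50)) == 1.0
        # the midpoint of the class centroids scores both classes equally
        # (holds for any shared SPD covariance when priors are equal)
        mid = model.class_means.mean(axis=0)
        s = mid @ model._coef + model._intercept
        assert s[0] == pytest.approx(s[1], abs=1e-6)

    def test_equal_means_gives_chance_accuracy(self, rng):
        X = rng.standard_normal((400, 3))
        y = np.array(["A", "B"] * 200, dtype=object)
        model = train_lda(X, y)
        acc = np.mean(predict_lda(model, X) == y)
        assert 0.35 < acc < 0.65

    def test_matches_explicit_discriminant_arithmetic(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0],
                      [4.0, 4.0], [5.0, 4.5]])
        y = np.array(["A", "A", "A", "B", "B"], dtype=object)
        model = train_lda(X, y)
        Sinv = np.linalg.inv(model.shared_covariance)
        for x in [np.array([0.2, 0.3]), np.array([4.4, 4.1]),
                  np.array([2.0, 2.0])]:
            scores = []
            for ci, g in enumerate(model.classes):
                mu = model.class_means[ci]
                scores.append(x @ Sinv @ mu - 0.5 * mu @ Sinv @ mu
                              + np.log(model.priors[ci]))
            assert predict_lda(model, x) == model.classes[int(np.argmax(scores))]

    def test_class_mean_classified_as_its_class(self, rng):
        X = np.concatenate([rng.standard_normal((100, 4)),
                            rng.standard_normal((100, 4)) + 8.0])
        y = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
        model = train_lda(X, y)
        assert predict_lda(model, model.class_means[1]) == "B"

    def test_dimension_mismatch_raises(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array(["A", "B"] * 20, dtype=object)
        model = train_lda(X, y)
        with pytest.raises(ValueError):
            predict_lda(model, np.zeros(5))

    def test_channel_major_orientation_accepted(self, rng):
        X = np.concatenate([rng.standard_normal((30, 5)),
                            rng.standard_normal((30, 5)) + 6.0])
        y = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        m1 = train_lda(X, y)
        m2 = train_lda(X.T, y)
        assert np.allclose(m1.class_means, m2.class_means)

    def test_covariance_positive_definite(self, rng):
        # more dimensions than frames per class: shrinkage must rescue SPD
        X = rng.standard_normal((30, 50))
        y = np.array(["A", "B", "C"] * 10, dtype=object)
        model = train_lda(X, y)
        evals = np.linalg.eigvalsh(model.shared_covariance)
        assert evals.min() > 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_lda(rng.standard_normal((10, 2)),
                      np.array(["A"] * 10, dtype=object))
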