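"""Gesture classifiers: the cascaded CNN and the LDA comparators.

The cascade mirrors how rest dominates a session: a small rest-state
detection network (fed normalised RMS images) first decides rest vs.
non-rest; only non-rest frames reach the gesture recognition network (fed
discharge-rate images for the cwCST model, or RMS images for the RMS-CNN
comparator), which outputs one of the nine active gestures.  Both networks
share the same convolutional trunk: two modules of [3x3 conv (stride 1,
same padding; 32 then 16 filters) -> batch norm -> ReLU -> 2x2 stride-1
zero-padded average pooling], then a flatten and fully connected head with
a log-softmax output.  Training uses Adam (initial learning rate 0.01),
minibatches of 1,000 frames, a negative log-likelihood loss, and keeps the
parameter state with the best validation accuracy over a stratified held-out
split of the training frames.

The comparators are multiclass LDA models over the flat 192-channel feature
vectors (all ten classes directly, no cascade) with a Ledoit-Wolf shrinkage
pooled covariance — 192-dimensional features from a limited number of frames
would otherwise be near-singular.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import train_test_split

from . import nnet
from .features import FrameDataset
from .montage import REST_ID

__all__ = [
    "TrainConfig",
    "CascadeModel",
    "LdaModel",
    "make_gesture_net",
    "make_rest_net",
    "train_net",
    "train_cascade",
    "predict",
    "predict_frames",
    "train_lda",
    "predict_lda",
    "gesture_sort_key",
]


def gesture_sort_key(g: str):
    """Canonical class order: numeric suffix when labels look like 'M7'."""
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", str(g))
    return (m.group(1), int(m.group(2))) if m else (str(g), -1)


@dataclass
class TrainConfig:
    """Optimisation settings for the cascade networks."""

    lr0: float = 0.01
    batch: int = 1000
    epochs: int = 100
    val_fraction: float = 0.1
    seed: int = 0
    early_stop: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")


def make_gesture_net(n_classes: int, input_shape: tuple,
                     rng: np.random.Generator) -> nnet.Sequential:
    """Conv trunk + flatten -> 128 -> n_classes head."""
    h, w = input_shape
    return nnet.Sequential(
        nnet.Conv2d(1, 32, rng), nnet.BatchNorm2d(32), nnet.ReLU(),
        nnet.AvgPool2x2(),
        nnet.Conv2d(32, 16, rng), nnet.BatchNorm2d(16), nnet.ReLU(),
        nnet.AvgPool2x2(),
        nnet.Flatten(),
        nnet.Linear(h * w * 16, 128, rng), nnet.ReLU(),
        nnet.Linear(128, n_classes, rng),
        nnet.LogSoftmax(),
    )


def make_rest_net(input_shape: tuple, rng: np.random.Generator
                  ) -> nnet.Sequential:
    """Conv trunk + flatten -> 64 -> 2 head (non-rest = 0, rest = 1)."""
    h, w = input_shape
    return nnet.Sequential(
        nnet.Conv2d(1, 32, rng), nnet.BatchNorm2d(32), nnet.ReLU(),
        nnet.AvgPool2x2(),
        nnet.Conv2d(32, 16, rng), nnet.BatchNorm2d(16), nnet.ReLU(),
        nnet.AvgPool2x2(),
        nnet.Flatten(),
        nnet.Linear(h * w * 16, 64, rng), nnet.ReLU(),
        nnet.Linear(64, 2, rng),
        nnet.LogSoftmax(),
    )


def predict_log_proba(net: nnet.Sequential, images: np.ndarray,
                      batch: int = 4096) -> np.ndarray:
    """Log-probabilities for a stack of (N, H, W) images, inference mode."""
    x = np.asarray(images, dtype=np.float32)[:, None, :, :]
    outs = [net.forward(x[i:i + batch], train=False)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty((0,))


def train_net(
    net: nnet.Sequential,
    images: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> list:
    """Minibatch Adam training with best-validation checkpointing.

    A stratified ``val_fraction`` split of the frames is held out; after each
    epoch the validation accuracy is evaluated and the earliest parameter
    state attaining the best accuracy is kept.  Once validation accuracy
    reaches 1.0 further epochs cannot change the kept state, so training
    stops early (disable with ``cfg.early_stop``).  Returns the training
    history as ``(epoch, mean_loss, val_accuracy)`` rows.
    """
    x = np.asarray(images, dtype=np.float32)[:, None, :, :]
    y = np.asarray(targets, dtype=np.intp)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=cfg.val_fraction,
        stratify=y, random_state=int(rng.integers(2**31 - 1)),
    )
    xtr, ytr = x[idx_tr], y[idx_tr]
    xval, yval = x[idx_val], y[idx_val]
    opt = nnet.Adam(net.params(), lr=cfg.lr0)
    best_acc, best_state = -1.0, None
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for b0 in range(0, len(order), cfg.batch):
            sel = order[b0:b0 + cfg.batch]
            logp = net.forward(xtr[sel], train=True)
            loss, grad = nnet.nll_loss(logp, ytr[sel])
            losses.append(loss)
            net.zero_grad()
            net.backward(grad)
            opt.step()
        val_pred = np.argmax(predict_log_proba(net, xval[:, 0]), axis=1)
        acc = float(np.mean(val_pred == yval))
        history.append((epoch, float(np.mean(losses)), acc))
        if acc > best_acc:
            best_acc, best_state = acc, net.state()
        if cfg.early_stop and best_acc >= 1.0:
            break
    net.load_state(best_state)
    return history


@dataclass
class CascadeModel:
    """Rest-detection network gating a 9-class gesture network."""

    rest_net: nnet.Sequential
    gesture_net: nnet.Sequential
    gesture_classes: list
    rest_id: str = REST_ID
    feature_kind: str = "cwcst_rate"
    history: dict = field(default_factory=dict)


def train_cascade(
    train_frames_rms: FrameDataset,
    train_frames_feat: FrameDataset,
    cfg: TrainConfig | None = None,
    rest_id: str = REST_ID,
    gesture_classes: list | None = None,
) -> CascadeModel:
    """Train both cascade stages on aligned RMS / feature frame datasets.

    The rest net learns rest-vs-nonrest over the RMS images; the gesture net
    learns the active-gesture classes over the feature images of non-rest
    frames.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(train_frames_rms.labels)
    if len(train_frames_rms) != len(train_frames_feat) or not np.array_equal(
            labels, np.asarray(train_frames_feat.labels)):
        raise ValueError("RMS and feature frame datasets must align")
    present = set(labels.tolist())
    if rest_id not in present:
        raise ValueError(f"class {rest_id!r} absent from training data")
    found = sorted(present - {rest_id}, key=gesture_sort_key)
    if gesture_classes is None:
        gesture_classes = found
    else:
        missing = sorted(set(gesture_classes) - present, key=gesture_sort_key)
        if missing:
            raise ValueError(
                f"class {missing[0]!r} absent from training data"
            )
    if len(gesture_classes) < 1:
        raise ValueError("no non-rest classes in training data")

    shape = train_frames_rms.images.shape[1:]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    rest_net = make_rest_net(shape, rng)
    gesture_net = make_gesture_net(len(gesture_classes), shape, rng)

    y_rest = (labels == rest_id).astype(np.intp)
    hist_rest = train_net(rest_net, train_frames_rms.images, y_rest, cfg, rng)

    mask = labels != rest_id
    class_idx = {g: i for i, g in enumerate(gesture_classes)}
    y_gest = np.array([class_idx[g] for g in labels[mask]], dtype=np.intp)
    hist_gest = train_net(
        gesture_net, train_frames_feat.images[mask], y_gest, cfg, rng
    )
    return CascadeModel(
        rest_net=rest_net,
        gesture_net=gesture_net,
        gesture_classes=list(gesture_classes),
        rest_id=rest_id,
        feature_kind=train_frames_feat.feature_kind,
        history={"rest": hist_rest, "gesture": hist_gest},
    )


def predict_frames(model: CascadeModel, rms_images: np.ndarray,
                   feat_images: np.ndarray) -> np.ndarray:
    """Cascade prediction for stacks of aligned RMS / feature images."""
    rms_images = np.atleast_3d(np.asarray(rms_images))
    feat_images = np.atleast_3d(np.asarray(feat_images))
    if rms_images.shape != feat_images.shape:
        raise ValueError("image stacks must share a shape")
    rest_lp = predict_log_proba(model.rest_net, rms_images)
    is_rest = np.argmax(rest_lp, axis=1) == 1
    out = np.full(len(rms_images), model.rest_id, dtype=object)
    if np.any(~is_rest):
        gest_lp = predict_log_proba(model.gesture_net, feat_images[~is_rest])
        picks = np.argmax(gest_lp, axis=1)
        out[~is_rest] = [model.gesture_classes[i] for i in picks]
    return out


def predict(model: CascadeModel, frame_rms: np.ndarray,
            frame_feat: np.ndarray) -> str:
    """Single-frame cascade prediction: rest, or the best active gesture."""
    frame_rms = np.asarray(frame_rms)
    if frame_rms.ndim != 2:
        raise ValueError("expected a single (H, W) image")
    return predict_frames(model, frame_rms[None], np.asarray(frame_feat)[None])[0]


# ---------------------------------------------------------------------------
# LDA comparators
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Gaussian classes with a shared (shrinkage) covariance."""

    classes: list
    class_means: np.ndarray
    shared_covariance: np.ndarray
    priors: np.ndarray
    _coef: np.ndarray = None
    _intercept: np.ndarray = None

    def __post_init__(self) -> None:
        if self._coef is None:
            # delta_c(x) = x^T S^-1 mu_c - 1/2 mu_c^T S^-1 mu_c + log pi_c
            sol = np.linalg.solve(self.shared_covariance, self.class_means.T)
            self._coef = sol  # (dim, n_classes)
            self._intercept = (
                -0.5 * np.sum(self.class_means.T * sol, axis=0)
                + np.log(self.priors)
            )

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


def _orient_frames_major(features: np.ndarray, labels: np.ndarray
                         ) -> np.ndarray:
    """Accept (n_frames, dim) or (dim, n_frames); labels disambiguate."""
    features = np.asarray(features, dtype=np.float64)
    n = len(labels)
    if features.shape[0] == n:
        return features
    if features.shape[1] == n:
        return features.T
    raise ValueError("feature matrix does not match label count")


def train_lda(features: np.ndarray, labels, shrinkage="auto") -> LdaModel:
    """Multiclass LDA with a pooled Ledoit-Wolf shrinkage covariance.

    ``shrinkage='auto'`` estimates the Ledoit-Wolf coefficient; a float in
    [0, 1] fixes the shrinkage toward the scaled identity; 0 requests the
    empirical covariance (automatically shrunk, with a warning, if singular).
    """
    labels = np.asarray(labels)
    X = _orient_frames_major(features, labels)
    classes = sorted(set(labels.tolist()), key=gesture_sort_key)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    means, resid, priors = [], [], []
    for g in classes:
        sel = X[labels == g]
        if len(sel) < 2:
            raise ValueError(f"class {g!r} needs at least 2 frames")
        means.append(sel.mean(axis=0))
        resid.append(sel - sel.mean(axis=0))
        priors.append(len(sel) / len(X))
    means = np.asarray(means)
    resid = np.concatenate(resid)
    if shrinkage == "auto":
        cov, _ = ledoit_wolf(resid, assume_centered=True)
    else:
        emp = resid.T @ resid / len(resid)
        lam = float(shrinkage)
        if lam == 0.0 and np.linalg.cond(emp) > 1e10:
            warnings.warn("singular pooled covariance; applying shrinkage",
                          stacklevel=2)
            lam = 0.1
        mu = np.trace(emp) / emp.shape[0]
        cov = (1 - lam) * emp + lam * mu * np.eye(emp.shape[0])
    return LdaModel(classes=classes, class_means=means,
                    shared_covariance=cov, priors=np.asarray(priors))


def predict_lda(model: LdaModel, feature: np.ndarray):
    """Class with the largest linear discriminant; vector or matrix input."""
    x = np.asarray(feature, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dim {x.shape[1]} != model dim {model.n_features}"
        )
    scores = x @ model._coef + model._intercept
    picks = np.argmax(scores, axis=1)
    out = np.array([model.classes[i] for i in picks], dtype=object)
    return out[0] if single else out
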