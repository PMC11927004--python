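"""Accuracy, confusion matrices, the k-trial sweep, and SI/RI metrics.

The separability index (SI) and repeatability index (RI) quantify feature
quality in Mahalanobis units relative to the pooled within-class covariance
S of the training features:

* ``SI_c = 1/2 * min_{c' != c} sqrt((mu_c - mu_c')^T S^-1 (mu_c - mu_c'))`` —
  half the distance from class c's centroid to its nearest other centroid;
  the mean over classes is the SI.  Larger = better separated gestures.
* ``RI_c = 1/2 * sqrt((mu_c,train - mu_c,test)^T S^-1 (mu_c,train -
  mu_c,test))`` — half the train/test centroid shift per class; the mean
  over classes is the RI.  Smaller = more repeatable features.

The pooled covariance uses the empirical estimate when well conditioned and
falls back to Ledoit-Wolf shrinkage otherwise, so SI keeps its exact affine
invariance on healthy data while remaining defined for rank-deficient
feature sets.

``trial_sweep`` runs the full recognition experiment: fit the decomposition
on the calibration trial, frame every other trial, train on the first k
non-calibration trials and test on the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf

from .decompose import DecompositionConfig, decompose_trial, fit_decomposition
from .features import (
    FrameConfig,
    FrameDataset,
    discharge_rate_frames,
    fit_rms_norm,
    frame_starts,
    label_frames,
    make_frame_dataset,
    rms_frames,
)
from .models import (
    TrainConfig,
    gesture_sort_key,
    predict_frames,
    predict_lda,
    train_cascade,
    train_lda,
)
from .montage import REST_ID, TrialSet
from .preprocess import PreprocessConfig, preprocess

__all__ = [
    "EvalReport",
    "ExperimentConfig",
    "TrialFeatures",
    "accuracy_and_confusion",
    "separability_index",
    "repeatability_index",
    "extract_trial_features",
    "prepare_session",
    "trial_sweep",
]


@dataclass
class EvalReport:
    """Results of one evaluation: accuracy, confusion, and feature metrics."""

    accuracy: float
    confusion: np.ndarray
    classes: list
    per_k_accuracy: dict = field(default_factory=dict)
    si: float | None = None
    ri: float | None = None


def accuracy_and_confusion(truth, pred, classes: list | None = None
                           ) -> EvalReport:
    """Fraction correct and a truth-by-prediction count matrix.

    Classes are ordered canonically (M1..M10) unless given explicitly.
    """
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if truth.size == 0:
        raise ValueError("empty input")
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    if classes is None:
        classes = sorted(set(truth.tolist()) | set(pred.tolist()),
                         key=gesture_sort_key)
    index = {g: i for i, g in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        conf[index[t], index[p]] += 1
    acc = float(np.trace(conf) / conf.sum())
    return EvalReport(accuracy=acc, confusion=conf, classes=list(classes))


# ---------------------------------------------------------------------------
# SI / RI
# ---------------------------------------------------------------------------

def _pooled_within_covariance(X: np.ndarray, labels: np.ndarray
                              ) -> np.ndarray:
    resid = []
    for g in np.unique(labels):
        sel = X[labels == g]
        resid.append(sel - sel.mean(axis=0))
    n_classes = len(resid)
    resid = np.concatenate(resid)
    # classic pooled estimator: sum of within-class scatter over (n - k)
    S = resid.T @ resid / max(len(resid) - n_classes, 1)
    if np.linalg.cond(S) > 1e10 or not np.all(np.isfinite(S)):
        S, _ = ledoit_wolf(resid, assume_centered=True)
    return S


def _mahalanobis_sq(delta: np.ndarray, S: np.ndarray) -> float:
    return float(delta @ np.linalg.solve(S, delta))


def separability_index(features: np.ndarray, labels) -> float:
    """Mean over classes of half the nearest-centroid Mahalanobis distance."""
    labels = np.asarray(labels)
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] != len(labels):
        X = X.T
    classes = sorted(set(labels.tolist()), key=gesture_sort_key)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    S = _pooled_within_covariance(X, labels)
    mus = {g: X[labels == g].mean(axis=0) for g in classes}
    si_vals = []
    for g in classes:
        d = min(
            np.sqrt(max(_mahalanobis_sq(mus[g] - mus[h], S), 0.0))
            for h in classes if h != g
        )
        si_vals.append(0.5 * d)
    return float(np.mean(si_vals))


def repeatability_index(train_features, train_labels, test_features,
                        test_labels) -> float:
    """Mean over classes of half the train/test centroid Mahalanobis shift.

    The covariance is pooled from the training features.  Classes missing
    from either set are skipped with a warning.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    Xtr = np.asarray(train_features, dtype=np.float64)
    Xte = np.asarray(test_features, dtype=np.float64)
    if Xtr.shape[0] != len(train_labels):
        Xtr = Xtr.T
    if Xte.shape[0] != len(test_labels):
        Xte = Xte.T
    S = _pooled_within_covariance(Xtr, train_labels)
    tr_classes = set(train_labels.tolist())
    te_classes = set(test_labels.tolist())
    skipped = (tr_classes | te_classes) - (tr_classes & te_classes)
    if skipped:
        warnings.warn(f"classes missing from one set skipped: {sorted(skipped)}",
                      stacklevel=2)
    ri_vals = []
    for g in sorted(tr_classes & te_classes, key=gesture_sort_key):
        delta = Xtr[train_labels == g].mean(axis=0) \
            - Xte[test_labels == g].mean(axis=0)
        ri_vals.append(0.5 * np.sqrt(max(_mahalanobis_sq(delta, S), 0.0)))
    if not ri_vals:
        raise ValueError("no class present in both sets")
    return float(np.mean(ri_vals))


# ---------------------------------------------------------------------------
# session orchestration: features per trial, k-trial sweep
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """All stage configurations of one recognition experiment."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    frames: FrameConfig = field(default_factory=FrameConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    feature_kind: str = "cwcst_rate"
    classifier: str = "cnn"
    rest_id: str = REST_ID

    def __post_init__(self) -> None:
        if self.feature_kind not in ("cwcst_rate", "rms"):
            raise ValueError("feature_kind: 'cwcst_rate' or 'rms'")
        if self.classifier not in ("cnn", "lda"):
            raise ValueError("classifier: 'cnn' or 'lda'")


@dataclass
class TrialFeatures:
    """Framed per-trial features: discharge rates, raw RMS, labels."""

    rates: np.ndarray          # (C, F) clamped discharge rates
    rms: np.ndarray            # (C, F) un-normalised RMS
    labels: np.ndarray         # (F,) gesture ids, "" where invalid
    valid: np.ndarray          # (F,) frames fully inside one interval
    frame_times: np.ndarray    # (F,) window-end times, s
    excluded: set
    montage: object


def extract_trial_features(rec, model, cfg: ExperimentConfig
                           ) -> TrialFeatures:
    """Preprocessed trial -> spike trains -> framed rate + RMS features."""
    spikes = decompose_trial(rec, model)
    rates = discharge_rate_frames(spikes, cfg.frames)
    rms = rms_frames(rec, FrameConfig(cfg.frames.window_ms, cfg.frames.step_ms,
                                      cfg.frames.rate_cap, rms_norm=None))
    win = cfg.frames.window_samples(rec.fs)
    step = cfg.frames.step_samples(rec.fs)
    starts = frame_starts(rec.n_samples, win, step)
    frame_times = (starts + win) / rec.fs
    labels, valid = label_frames(rec, frame_times, win / rec.fs)
    return TrialFeatures(
        rates=rates, rms=rms, labels=labels, valid=valid,
        frame_times=frame_times,
        excluded=set(rec.excluded_channels), montage=rec.montage,
    )


def prepare_session(session: TrialSet, cfg: ExperimentConfig
                    ) -> tuple[object, list]:
    """Preprocess all trials, fit the decomposition on calibration, frame all.

    Returns ``(decomposition_model, per-trial TrialFeatures)`` where the
    calibration trial's entry is ``None``.
    """
    calib_idx = session.calibration_index
    calib = preprocess(session.trials[calib_idx], cfg.preprocess)
    model = fit_decomposition(calib, cfg.decomposition)
    del calib
    feats: list = [None] * len(session.trials)
    for i, rec in enumerate(session.trials):
        if i == calib_idx:
            continue
        clean = preprocess(rec, cfg.preprocess)
        feats[i] = extract_trial_features(clean, model, cfg)
        del clean
    return model, feats


def _frame_images(tf: TrialFeatures, kind: str, frame_cfg: FrameConfig,
                  rms_norm: np.ndarray) -> FrameDataset:
    from .features import build_images
    feats = tf.rates if kind == "cwcst_rate" else _normed_rms(tf, rms_norm)
    imgs = build_images(feats, tf.montage, tf.excluded)
    v = tf.valid
    return FrameDataset(images=imgs[v], labels=np.asarray(tf.labels[v]),
                        frame_times=tf.frame_times[v], feature_kind=kind)


def _normed_rms(tf: TrialFeatures, rms_norm: np.ndarray) -> np.ndarray:
    norm = rms_norm.copy()
    norm[norm == 0] = 1.0
    return tf.rms / norm[:, None]


def trial_sweep(
    session: TrialSet,
    k: int,
    cfg: ExperimentConfig,
    prepared: tuple | None = None,
    return_details: bool = False,
):
    """Train on the first k non-calibration trials, test on the remainder.

    ``prepared`` may carry the output of :func:`prepare_session` to reuse the
    decomposition and framing across several k (they do not depend on the
    train/test split).  Returns the test accuracy, or a detail dict when
    ``return_details`` is set.
    """
    non_calib = session.non_calibration_indices()
    if k < 1 or k >= len(non_calib):
        raise ValueError(
            f"k={k} requires between 1 and {len(non_calib) - 1} training "
            "trials with at least one left for testing"
        )
    model, feats = prepared if prepared is not None else \
        prepare_session(session, cfg)
    train_ids = non_calib[:k]
    test_ids = non_calib[k:]

    rms_norm = fit_rms_norm([feats[i].rms for i in train_ids])

    def stack(ids, kind):
        parts = [_frame_images(feats[i], kind, cfg.frames, rms_norm)
                 for i in ids]
        return FrameDataset(
            images=np.concatenate([p.images for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            frame_times=np.concatenate([p.frame_times for p in parts]),
            feature_kind=kind,
        )

    train_rms = stack(train_ids, "rms")
    test_rms = stack(test_ids, "rms")
    if cfg.feature_kind == "rms":
        train_feat, test_feat = train_rms, test_rms
    else:
        train_feat = stack(train_ids, "cwcst_rate")
        test_feat = stack(test_ids, "cwcst_rate")

    if cfg.classifier == "cnn":
        cascade = train_cascade(train_rms, train_feat, cfg.training,
                                rest_id=cfg.rest_id)
        pred = predict_frames(cascade, test_rms.images, test_feat.images)
        fitted = cascade
    else:
        Xtr = train_feat.images.reshape(len(train_feat), -1)
        Xte = test_feat.images.reshape(len(test_feat), -1)
        lda = train_lda(Xtr, train_feat.labels)
        pred = predict_lda(lda, Xte)
        fitted = lda

    report = accuracy_and_confusion(test_feat.labels, pred)
    if not return_details:
        return report.accuracy
    return {
        "accuracy": report.accuracy,
        "report": report,
        "model": fitted,
        "train_feat": train_feat,
        "test_feat": test_feat,
        "train_rms": train_rms,
        "test_rms": test_rms,
        "pred": pred,
    }
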