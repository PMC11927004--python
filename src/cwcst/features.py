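"""Framed feature extraction and 8x24 image construction.

Two per-channel features are computed over a 200-ms sliding window advanced
in 50-ms steps: the cumulative discharge rate of the decomposed spike trains
(clamped at a maximum rate to suppress paradoxical firings) and the classic
RMS amplitude (normalised per channel by its maximum over the training
trials).  Each frame's 192 values are then arranged on the electrode grid,
yielding one 8x24 feature image per frame; frames are labelled by the gesture
covering the window centre, and frames that straddle a gesture transition are
dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montage import EmgRecording, MontageLayout
from .decompose import SpikeTrainMatrix

__all__ = [
    "FrameConfig",
    "FrameDataset",
    "frame_count",
    "frame_starts",
    "discharge_rate_frames",
    "rms_frames",
    "fit_rms_norm",
    "build_images",
    "label_frames",
    "make_frame_dataset",
]


@dataclass
class FrameConfig:
    """Sliding-window framing parameters.

    ``rate_cap`` clamps the per-channel cumulative discharge rate
    (firings/s); cumulative trains pool several motor units, so the cap sits
    well above single-unit physiological rates.  ``rms_norm`` holds the
    per-channel normalisation constants fitted on training trials.
    """

    window_ms: float = 200.0
    step_ms: float = 50.0
    rate_cap: float = 100.0
    rms_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.step_ms <= self.window_ms):
            raise ValueError("need 0 < step_ms <= window_ms")
        if self.rate_cap <= 0:
            raise ValueError("rate_cap must be positive")

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step_ms * fs / 1000.0))


@dataclass
class FrameDataset:
    """Per-frame feature images with labels and window-end times."""

    images: np.ndarray
    labels: np.ndarray
    frame_times: np.ndarray
    feature_kind: str

    def __post_init__(self) -> None:
        if self.images.ndim != 3:
            raise ValueError("images must be (frames, rows, cols)")
        if not (len(self.images) == len(self.labels) == len(self.frame_times)):
            raise ValueError("frames, labels and times must align")

    def __len__(self) -> int:
        return len(self.images)


def frame_count(n_samples: int, window: int, step: int) -> int:
    """Number of full windows: ``floor((T - window) / step) + 1`` (0 if T < window)."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def frame_starts(n_samples: int, window: int, step: int) -> np.ndarray:
    return np.arange(frame_count(n_samples, window, step)) * step


def _window_sums(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Per-channel sums over sliding windows; x is (C, T), result (C, F)."""
    starts = frame_starts(x.shape[1], window, step)
    cs = np.concatenate(
        [np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1, dtype=np.float64)],
        axis=1,
    )
    return cs[:, starts + window] - cs[:, starts]


def discharge_rate_frames(spikes: SpikeTrainMatrix, cfg: FrameConfig | None = None
                          ) -> np.ndarray:
    """Clamped per-channel discharge rate (firings/s), shape (C, frames)."""
    cfg = cfg or FrameConfig()
    win = cfg.window_samples(spikes.fs)
    step = cfg.step_samples(spikes.fs)
    counts = _window_sums(spikes.spikes, win, step)
    rates = counts / (win / spikes.fs)
    return np.minimum(rates, cfg.rate_cap)


def rms_frames(rec: EmgRecording, cfg: FrameConfig | None = None) -> np.ndarray:
    """Per-channel windowed RMS, divided by ``cfg.rms_norm`` when fitted."""
    cfg = cfg or FrameConfig()
    win = cfg.window_samples(rec.fs)
    step = cfg.step_samples(rec.fs)
    x = np.asarray(rec.samples.T, dtype=np.float64)
    ms = _window_sums(x * x, win, step) / win
    rms = np.sqrt(ms)
    if cfg.rms_norm is not None:
        norm = np.asarray(cfg.rms_norm, dtype=np.float64).copy()
        if np.any(norm == 0):
            warnings.warn("zero RMS normalisation entries replaced by 1",
                          stacklevel=2)
            norm[norm == 0] = 1.0
        rms = rms / norm[:, None]
    return rms


def fit_rms_norm(rms_feature_matrices: list) -> np.ndarray:
    """Per-channel maximum windowed RMS over the training trials."""
    stacked = np.concatenate([np.asarray(m) for m in rms_feature_matrices],
                             axis=1)
    return stacked.max(axis=1)


def build_images(features: np.ndarray, montage: MontageLayout,
                 excluded: set | None = None) -> np.ndarray:
    """Arrange per-channel features on the electrode grid, one image per frame.

    Excluded channels are filled with the mean of their available (non-
    excluded) 8-connected grid neighbours, 0 if none — images must keep a
    fixed shape for the classifier.
    """
    features = np.asarray(features)
    if features.shape[0] != montage.n_channels:
        raise ValueError(
            f"{features.shape[0]} feature channels, montage has "
            f"{montage.n_channels}"
        )
    excluded = set() if excluded is None else set(excluded)
    grid = montage.grid_index
    imgs = features[grid].transpose(2, 0, 1).astype(np.float32)  # (F, R, C)
    if not excluded:
        return imgs
    excl_mask = np.zeros(montage.n_channels, dtype=bool)
    excl_mask[list(excluded)] = True
    grid_excl = excl_mask[grid]
    for r, c in zip(*np.nonzero(grid_excl)):
        vals = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if montage.circular:
                    cc %= montage.n_cols
                if 0 <= rr < montage.n_rows and 0 <= cc < montage.n_cols \
                        and not grid_excl[rr, cc]:
                    vals.append(imgs[:, rr, cc])
        imgs[:, r, c] = np.mean(vals, axis=0) if vals else 0.0
    return imgs


def label_frames(rec: EmgRecording, frame_times: np.ndarray, window_s: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame gesture labels from the recording's intervals.

    ``frame_times`` are window-end times.  A frame takes the label of the
    gesture covering its centre; frames not fully inside a single labelled
    interval (transition-straddling or uncovered) are marked invalid.
    Returns ``(labels, valid)``; labels of invalid frames are ``""``.
    """
    frame_times = np.asarray(frame_times, dtype=np.float64)
    labels = np.full(frame_times.shape, "", dtype=object)
    valid = np.zeros(frame_times.shape, dtype=bool)
    for f, end in enumerate(frame_times):
        start = end - window_s
        center = end - window_s / 2.0
        for a, b, g in rec.labels:
            if a <= center < b:
                if start >= a - 1e-9 and end <= b + 1e-9:
                    labels[f] = g
                    valid[f] = True
                break
    return labels, valid


def make_frame_dataset(
    features: np.ndarray,
    rec: EmgRecording,
    cfg: FrameConfig,
    feature_kind: str,
    keep_invalid: bool = False,
) -> FrameDataset:
    """Images + labels + times for one trial's feature matrix (C, frames)."""
    win = cfg.window_samples(rec.fs)
    step = cfg.step_samples(rec.fs)
    starts = frame_starts(rec.n_samples, win, step)
    frame_times = (starts + win) / rec.fs
    labels, valid = label_frames(rec, frame_times, win / rec.fs)
    imgs = build_images(features, rec.montage, rec.excluded_channels)
    if not keep_invalid:
        imgs, labels, frame_times = imgs[valid], labels[valid], frame_times[valid]
    return FrameDataset(images=imgs, labels=np.asarray(labels, dtype=object),
                        frame_times=frame_times, feature_kind=feature_kind)
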