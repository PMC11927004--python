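"""Denoising and abnormal-channel screening.

Standard surface-EMG conditioning: a zero-phase 20-450 Hz Butterworth
band-pass removes movement artefact and high-frequency noise, and a cascade
of zero-phase IIR notches at 50 Hz and its harmonics (a notching-comb)
suppresses power-line interference.  Channels whose whole-trial RMS is a
robust outlier (or exactly zero) are flagged as abnormal and excluded from
decomposition; the imaging stage later fills them from grid neighbours.

Zero-phase (forward-backward) filtering is used throughout so spike timing
is not skewed before decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import EmgRecording

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "comb_notch",
    "screen_channels",
    "preprocess",
]


class ConfigurationError(ValueError):
    pass


class DataQualityError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and screening parameters.

    ``band_lo``/``band_hi`` bound the EMG pass-band in Hz, ``notch_base`` is
    the power-line fundamental whose harmonics up to ``band_hi`` are notched
    with quality factor ``notch_q``.  ``screen_k`` is the robust-outlier
    multiplier: channels with RMS outside median +- k*MAD are abnormal.
    """

    band_lo: float = 20.0
    band_hi: float = 450.0
    notch_base: float = 50.0
    notch_q: float = 30.0
    filter_order: int = 4
    screen_k: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.band_lo < self.band_hi):
            raise ConfigurationError("need 0 < band_lo < band_hi")

    def notch_frequencies(self) -> np.ndarray:
        return np.arange(self.notch_base, self.band_hi + 1e-9, self.notch_base)


def _check_fs(fs: float, cfg: PreprocessConfig) -> None:
    if fs <= 2 * cfg.band_hi:
        raise ConfigurationError(
            f"fs={fs} Hz cannot support a {cfg.band_hi} Hz pass-band edge"
        )


def _bandpass_sos(fs: float, cfg: PreprocessConfig) -> np.ndarray:
    return signal.butter(cfg.filter_order, [cfg.band_lo, cfg.band_hi],
                         btype="bandpass", fs=fs, output="sos")


def _notch_sos(fs: float, cfg: PreprocessConfig) -> np.ndarray:
    sections = []
    for f0 in cfg.notch_frequencies():
        b, a = signal.iirnotch(f0, cfg.notch_q, fs=fs)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def _zero_phase(samples: np.ndarray, sos: np.ndarray) -> np.ndarray:
    # 'even' padding mirrors the signal at the edges (reflect padding)
    out = signal.sosfiltfilt(sos, samples, axis=0, padtype="even")
    return out.astype(samples.dtype, copy=False)


def bandpass_filter(rec: EmgRecording, cfg: PreprocessConfig | None = None
                    ) -> EmgRecording:
    """Zero-phase Butterworth band-pass (20-450 Hz by default), channel-wise."""
    cfg = cfg or PreprocessConfig()
    _check_fs(rec.fs, cfg)
    return rec.with_samples(_zero_phase(rec.samples, _bandpass_sos(rec.fs, cfg)))


def comb_notch(rec: EmgRecording, cfg: PreprocessConfig | None = None
               ) -> EmgRecording:
    """Zero-phase notch cascade at the power-line fundamental and harmonics."""
    cfg = cfg or PreprocessConfig()
    return rec.with_samples(_zero_phase(rec.samples, _notch_sos(rec.fs, cfg)))


def screen_channels(rec: EmgRecording, cfg: PreprocessConfig | None = None
                    ) -> set:
    """Flag channels whose whole-trial RMS is a robust outlier or zero.

    The rule is median +- ``screen_k`` * MAD over the per-channel RMS values,
    plus an explicit dead-channel (all-zero) check.  More than half the
    channels failing indicates a data-quality problem and raises.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(rec.samples, dtype=np.float64)
    rms = np.sqrt(np.mean(x**2, axis=0))
    med = np.median(rms)
    mad = np.median(np.abs(rms - med))
    bad = (rms == 0) | (np.abs(rms - med) > cfg.screen_k * mad)
    flagged = {int(c) for c in np.nonzero(bad)[0]}
    if len(flagged) > rec.n_channels / 2:
        raise DataQualityError(
            f"{len(flagged)}/{rec.n_channels} channels flagged abnormal"
        )
    return flagged


def preprocess(rec: EmgRecording, cfg: PreprocessConfig | None = None,
               screen: bool = True) -> EmgRecording:
    """Band-pass + comb notch, then store screened channels on the recording."""
    cfg = cfg or PreprocessConfig()
    _check_fs(rec.fs, cfg)
    sos = np.vstack([_bandpass_sos(rec.fs, cfg), _notch_sos(rec.fs, cfg)])
    out = rec.with_samples(_zero_phase(rec.samples, sos))
    if screen:
        out.excluded_channels = set(rec.excluded_channels) | screen_channels(out, cfg)
    return out
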