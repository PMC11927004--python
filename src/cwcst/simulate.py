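"""Synthetic HD-sEMG sessions from a convolutive mixture model.

Surface EMG is modelled as ``X(t) = H * S(t) + w(t)``: every motor unit (MU)
contributes a spatially distributed action-potential waveform (MUAP) convolved
with its spike train, plus additive white Gaussian noise.  The MUAP conducts
along the muscle-fibre direction with little attenuation and decays quickly
across fibres, which is exactly the spatial structure the downstream spike
detector exploits.  Gestures are given disjoint contiguous pools of MU centres
on the electrode grid, so each gesture lights up a distinct region — the
spatial activation pattern the imaging classifier learns.

The default protocol mirrors the experimental design the package targets:
10 gestures (M10 = rest), 10-s sustained motions separated by 5-s rests,
randomised motion order with rest performed last, 8 repeated trials of 150 s.

Ground-truth spike trains are returned alongside every synthesised trial so
decomposition accuracy can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .montage import (
    GESTURES,
    REST_ID,
    EmgRecording,
    MontageLayout,
    TrialSet,
    default_montage,
)

__all__ = [
    "MuapTemplate",
    "MotorUnitSpec",
    "SimulationConfig",
    "GroundTruth",
    "biphasic_kernel",
    "generate_spike_train",
    "synthesize_trial",
    "generate_session",
    "default_motor_units",
    "default_simulation",
    "noise_sd_for_snr",
]


class ConfigurationError(ValueError):
    pass


def biphasic_kernel(fs: float, duration_ms: float = 10.0) -> np.ndarray:
    """Biphasic MUAP base waveform: first derivative of a Gaussian.

    Length ``round(duration_ms * fs / 1000)`` samples, peak amplitude 1.
    """
    length = max(int(round(duration_ms * fs / 1000.0)), 5)
    t = np.arange(length) - (length - 1) / 2.0
    sigma = length / 6.0
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return (w / np.abs(w).max()).astype(np.float64)


@dataclass
class MuapTemplate:
    """Spatially distributed MUAP: scaled copies of one biphasic kernel.

    The per-cell gain is ``amplitude * decay_along**|d_along| *
    decay_across**|d_across|`` where the along-fibre axis is the grid row
    direction by default.  ``decay_across < decay_along`` encodes the faster
    attenuation perpendicular to the fibres.
    """

    length_samples: int
    center: tuple
    amplitude: float = 1.0
    fiber_axis: str = "row"
    decay_along: float = 0.85
    decay_across: float = 0.5
    waveform: np.ndarray | None = None
    min_gain: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.decay_across < self.decay_along <= 1.0):
            raise ConfigurationError(
                "require 0 < decay_across < decay_along <= 1"
            )
        if self.fiber_axis not in ("row", "col"):
            raise ConfigurationError("fiber_axis must be 'row' or 'col'")
        if self.waveform is None:
            # default kernel at the canonical 2,048 Hz time base
            t = np.arange(self.length_samples) - (self.length_samples - 1) / 2.0
            sigma = self.length_samples / 6.0
            w = -t * np.exp(-(t**2) / (2 * sigma**2))
            self.waveform = w / np.abs(w).max()
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.waveform.shape != (self.length_samples,):
            raise ConfigurationError("waveform length mismatch")

    def spatial_gain(self, d_row: int, d_col: int) -> float:
        if self.fiber_axis == "row":
            d_along, d_across = d_row, d_col
        else:
            d_along, d_across = d_col, d_row
        return (
            self.amplitude
            * self.decay_along ** abs(d_along)
            * self.decay_across ** abs(d_across)
        )

    def footprint(self, montage: MontageLayout) -> tuple[np.ndarray, np.ndarray, bool]:
        """Channels reached by this MUAP and their gains.

        Returns ``(channels, gains, clipped)``; ``clipped`` is True when part
        of the footprint falls outside the grid (that energy is discarded).
        """
        r0, c0 = self.center
        if self.fiber_axis == "row":
            dec_r, dec_c = self.decay_along, self.decay_across
        else:
            dec_r, dec_c = self.decay_across, self.decay_along

        def radius(decay: float) -> int:
            if decay >= 1.0:
                return 10**9
            return int(np.floor(np.log(self.min_gain) / np.log(decay)))

        rad_r, rad_c = radius(dec_r), radius(dec_c)
        rows = np.arange(max(0, r0 - rad_r), min(montage.n_rows, r0 + rad_r + 1))
        cols = np.arange(max(0, c0 - rad_c), min(montage.n_cols, c0 + rad_c + 1))
        clipped = (r0 - rad_r < 0 or r0 + rad_r >= montage.n_rows
                   or c0 - rad_c < 0 or c0 + rad_c >= montage.n_cols)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        gains = (
            self.amplitude
            * dec_r ** np.abs(rr - r0)
            * dec_c ** np.abs(cc - c0)
        ).ravel()
        keep = gains >= self.min_gain * self.amplitude - 1e-12
        grid = montage.grid_index
        channels = grid[rr.ravel()[keep], cc.ravel()[keep]]
        return channels, gains[keep], clipped


@dataclass
class MotorUnitSpec:
    """One motor unit: its MUAP template, firing statistics, and recruitment."""

    template: MuapTemplate
    mean_rate: float
    isi_cv: float = 0.15
    recruitment: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ConfigurationError("mean_rate must be positive")
        if self.isi_cv < 0:
            raise ConfigurationError("isi_cv must be non-negative")
        self.recruitment = set(self.recruitment)


@dataclass
class SimulationConfig:
    """Study-protocol and generator settings.

    Defaults reproduce the experimental timing: 10-s motions, 5-s inter-motion
    rests, 8 trials, gestures M1..M10 with M10 the rest state, 2,048 Hz.
    ``trial_gain_jitter`` (lognormal SD of a per-trial global gain) and
    ``rate_jitter`` (uniform ±fraction on each MU's rate per trial) emulate
    the session-to-session variability of real recordings.
    """

    motor_units: list
    fs: float = 2048.0
    montage: MontageLayout = field(default_factory=default_montage)
    noise_sd: float = 0.1
    motion_duration_s: float = 10.0
    rest_duration_s: float = 5.0
    n_trials: int = 8
    gesture_ids: tuple = GESTURES
    rest_id: str = REST_ID
    seed: int = 0
    trial_gain_jitter: float = 0.1
    rate_jitter: float = 0.15

    def __post_init__(self) -> None:
        if self.fs <= 2 * 450:
            raise ConfigurationError(
                "fs must exceed 900 Hz to support the 20-450 Hz band"
            )
        for mu in self.motor_units:
            if self.rest_id in mu.recruitment:
                raise ConfigurationError("the rest gesture must recruit no MUs")

    @property
    def active_gestures(self) -> list:
        return [g for g in self.gesture_ids if g != self.rest_id]


@dataclass
class GroundTruth:
    """Planted discharges for one synthesised trial.

    ``spike_trains`` is a sparse binary MU x time matrix; ``channel_truth``
    assigns each MU's discharges to its centre channel (sparse binary
    channel x time).  ``center_channels[j]`` is MU ``j``'s centre channel.
    """

    spike_trains: sp.csr_matrix
    channel_truth: sp.csr_matrix
    center_channels: np.ndarray

    def mu_spike_times(self, mu: int) -> np.ndarray:
        return self.spike_trains.getrow(mu).indices.copy()

    def channel_spike_times(self, channel: int) -> np.ndarray:
        return self.channel_truth.getrow(channel).indices.copy()


def generate_spike_train(
    mu: MotorUnitSpec, duration_s: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Renewal-process spike train as a binary sample vector.

    Inter-spike intervals are Gaussian with mean ``1/mean_rate`` and SD
    ``isi_cv/mean_rate``, truncated below at twice the MUAP length (an
    absolute refractory floor).  The first spike falls one full ISI after
    t = 0, so a zero-jitter unit produces a deterministic comb.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    refractory_s = 2.0 * mu.template.length_samples / fs
    mean_isi = 1.0 / mu.mean_rate
    if mean_isi < refractory_s:
        raise ConfigurationError(
            f"mean rate {mu.mean_rate} Hz violates the refractory floor of "
            f"{refractory_s * 1e3:.1f} ms"
        )
    n_samples = int(round(duration_s * fs))
    times = _spike_times(mu, duration_s, fs, rng)
    train = np.zeros(n_samples, dtype=np.uint8)
    train[times] = 1
    return train


def _spike_times(
    mu: MotorUnitSpec,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
) -> np.ndarray:
    """Sample indices of discharges within ``[0, duration_s)``."""
    rate = mu.mean_rate * rate_scale
    mean_isi = 1.0 / rate
    sd_isi = mu.isi_cv / rate
    refractory_s = 2.0 * mu.template.length_samples / fs
    # draw a safe surplus of intervals, extend in the unlikely shortfall
    n_guess = int(duration_s * rate * 1.5) + 10
    t, times = 0.0, []
    while True:
        isis = mean_isi + sd_isi * rng.standard_normal(n_guess)
        np.maximum(isis, refractory_s, out=isis)
        cum = t + np.cumsum(isis)
        inside = cum < duration_s
        times.append(cum[inside])
        if not inside.all():
            break
        t = cum[-1]
    times = np.concatenate(times)
    return np.unique((times * fs).astype(np.intp))


def _build_label_intervals(cfg: SimulationConfig, gesture_sequence: list) -> list:
    labels, t = [], 0.0
    for g in gesture_sequence:
        labels.append((t, t + cfg.motion_duration_s, g))
        t += cfg.motion_duration_s
        labels.append((t, t + cfg.rest_duration_s, cfg.rest_id))
        t += cfg.rest_duration_s
    merged = [labels[0]]
    for a, b, g in labels[1:]:  # adjacent same-gesture intervals coalesce
        pa, pb, pg = merged[-1]
        if g == pg and abs(a - pb) < 1e-9:
            merged[-1] = (pa, b, g)
        else:
            merged.append((a, b, g))
    return merged


def synthesize_trial(
    cfg: SimulationConfig,
    gesture_sequence: list,
    rng: np.random.Generator,
) -> tuple[EmgRecording, GroundTruth]:
    """One trial of the convolutive mixture: MUAPs * spikes + noise.

    Each labelled motion interval recruits exactly the MUs whose
    ``recruitment`` set contains that gesture; rest intervals are silent.
    A per-trial global gain and per-MU rate scale are drawn from ``rng``
    (see :class:`SimulationConfig`).
    """
    montage = cfg.montage
    labels = _build_label_intervals(cfg, gesture_sequence)
    n_samples = int(round(labels[-1][1] * cfg.fs))
    # pin the final interval to the sample-quantised duration
    labels[-1] = (labels[-1][0], n_samples / cfg.fs, labels[-1][2])
    samples = np.zeros((n_samples, montage.n_channels), dtype=np.float32)

    gain = float(np.exp(cfg.trial_gain_jitter * rng.standard_normal())) \
        if cfg.trial_gain_jitter > 0 else 1.0
    rate_scales = 1.0 + cfg.rate_jitter * rng.uniform(-1, 1, len(cfg.motor_units)) \
        if cfg.rate_jitter > 0 else np.ones(len(cfg.motor_units))

    n_clipped = 0
    mu_times = [[] for _ in cfg.motor_units]
    for a, b, g in labels:
        if g == cfg.rest_id:
            continue
        start = int(round(a * cfg.fs))
        stop = int(round(b * cfg.fs))
        seg_len = stop - start
        for j, mu in enumerate(cfg.motor_units):
            if g not in mu.recruitment:
                continue
            times = _spike_times(mu, seg_len / cfg.fs, cfg.fs, rng,
                                 rate_scale=float(rate_scales[j]))
            if times.size == 0:
                continue
            mu_times[j].append(times + start)
            channels, gains, clipped = mu.template.footprint(montage)
            n_clipped += bool(clipped)
            L = mu.template.length_samples
            impulse = np.zeros(seg_len, dtype=np.float64)
            impulse[times] = 1.0
            sig = np.convolve(impulse, mu.template.waveform)[:seg_len]
            seg = sig[:, None] * (gain * gains)[None, :]
            samples[start:stop, channels] += seg.astype(np.float32)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} MUAP footprints extend beyond the electrode grid; "
            "out-of-grid energy discarded", stacklevel=2)

    if cfg.noise_sd > 0:
        samples += rng.standard_normal(samples.shape, dtype=np.float32) \
            * np.float32(cfg.noise_sd)

    rec = EmgRecording(samples, cfg.fs, montage, labels)
    truth = _assemble_truth(cfg, mu_times, n_samples)
    return rec, truth


def _assemble_truth(cfg: SimulationConfig, mu_times: list, n_samples: int
                    ) -> GroundTruth:
    montage = cfg.montage
    grid = montage.grid_index
    centers = np.array(
        [grid[mu.template.center] for mu in cfg.motor_units], dtype=np.intp
    )
    rows_mu, rows_ch, cols = [], [], []
    for j, chunks in enumerate(mu_times):
        if not chunks:
            continue
        t = np.concatenate(chunks)
        cols.append(t)
        rows_mu.append(np.full(t.size, j, dtype=np.intp))
        rows_ch.append(np.full(t.size, centers[j], dtype=np.intp))
    if cols:
        cols = np.concatenate(cols)
        rows_mu = np.concatenate(rows_mu)
        rows_ch = np.concatenate(rows_ch)
    else:
        cols = rows_mu = rows_ch = np.array([], dtype=np.intp)
    ones = np.ones(cols.size, dtype=np.uint8)
    spike_trains = sp.csr_matrix(
        (ones, (rows_mu, cols)), shape=(len(cfg.motor_units), n_samples)
    )
    channel_truth = sp.csr_matrix(
        (ones, (rows_ch, cols)), shape=(montage.n_channels, n_samples)
    )
    channel_truth.data[:] = 1  # coincident discharges collapse to binary
    return GroundTruth(spike_trains, channel_truth, centers)


def generate_session(cfg: SimulationConfig) -> tuple[TrialSet, list]:
    """A full protocol session: ``n_trials`` trials plus per-trial truth.

    Motion order is re-randomised per trial with the rest state last; one
    randomly chosen trial is tagged ``calibration``, the remainder ``train``
    (re-taggable downstream).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    calib = int(rng.integers(cfg.n_trials))
    active = cfg.active_gestures
    trials, truths, roles = [], [], []
    for i in range(cfg.n_trials):
        order = [active[k] for k in rng.permutation(len(active))]
        order.append(cfg.rest_id)
        rec, truth = synthesize_trial(cfg, order, rng)
        trials.append(rec)
        truths.append(truth)
        roles.append("calibration" if i == calib else "train")
    return TrialSet(trials, roles), truths


def default_motor_units(
    montage: MontageLayout,
    rng: np.random.Generator,
    gestures: list | None = None,
    n_per_gesture: int = 10,
    rate_range: tuple = (8.0, 15.0),
    isi_cv: float = 0.15,
    amplitude_range: tuple = (0.8, 1.2),
    decay_along: float = 0.85,
    decay_across: float = 0.5,
    muap_ms: float = 10.0,
    fs: float = 2048.0,
) -> list:
    """MU population with one contiguous column pool per active gesture.

    The grid's columns are split into as many contiguous bands as there are
    active gestures; each gesture's MU centres are distinct cells drawn
    uniformly from its band, giving the disjoint spatial activation pools
    that make gestures separable in the discharge-rate images.
    """
    if gestures is None:
        gestures = [g for g in GESTURES if g != REST_ID]
    n_g = len(gestures)
    length = max(int(round(muap_ms * fs / 1000.0)), 5)
    bounds = np.linspace(0, montage.n_cols, n_g + 1).round().astype(int)
    mus = []
    for gi, g in enumerate(gestures):
        lo, hi = bounds[gi], bounds[gi + 1]
        cells = [(r, c) for r in range(montage.n_rows) for c in range(lo, hi)]
        if n_per_gesture > len(cells):
            raise ConfigurationError(
                f"pool for {g} has only {len(cells)} cells"
            )
        pick = rng.choice(len(cells), size=n_per_gesture, replace=False)
        for p in pick:
            tmpl = MuapTemplate(
                length_samples=length,
                center=cells[p],
                amplitude=float(rng.uniform(*amplitude_range)),
                decay_along=decay_along,
                decay_across=decay_across,
            )
            mus.append(MotorUnitSpec(
                template=tmpl,
                mean_rate=float(rng.uniform(*rate_range)),
                isi_cv=isi_cv,
                recruitment={g},
            ))
    return mus


def default_simulation(seed: int = 0, n_per_gesture: int = 10,
                       **overrides) -> SimulationConfig:
    """The default synthetic study: full protocol on the 192-channel montage."""
    montage = overrides.pop("montage", default_montage())
    fs = overrides.pop("fs", 2048.0)
    gesture_ids = tuple(overrides.pop("gesture_ids", GESTURES))
    rest_id = overrides.pop("rest_id", REST_ID)
    active = [g for g in gesture_ids if g != rest_id]
    placement_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC57]))
    mus = default_motor_units(montage, placement_rng, gestures=active,
                              n_per_gesture=n_per_gesture, fs=fs)
    return SimulationConfig(motor_units=mus, fs=fs, montage=montage,
                            gesture_ids=gesture_ids, rest_id=rest_id,
                            seed=seed, **overrides)


def noise_sd_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the requested SNR against ``clean``'s active power.

    Signal power is averaged over samples where any channel is non-zero, so
    the silent rest periods do not dilute the reference level.
    """
    active = np.any(clean != 0, axis=1)
    if not active.any():
        raise ConfigurationError("clean signal is identically zero")
    p_sig = float(np.mean(np.asarray(clean[active], dtype=np.float64) ** 2))
    return float(np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)))
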