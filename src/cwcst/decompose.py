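"""Channel-wise cumulative spike-train decomposition.

The decomposition treats multichannel surface EMG as a convolutive mixture of
motor-unit action potentials (MUAPs) and recovers, per recording channel, the
cumulative discharge timings of the motor units closest to that electrode.
It runs in four steps, fitted once on a calibration trial:

1. **ZCA whitening** — ``W = Sigma^(-1/2) = U L^(-1/2) U^T`` from the channel
   covariance; whitened signals ``Z(t) = W X(t)`` live in Mahalanobis space
   where inter-channel correlation no longer masks individual discharges.
2. **Extension / energy** — the R-sample sliding sum of squares
   ``e_i(t) = sum_{r=1..R} z_i(t - r + 1)^2`` (the energy of the R-delayed
   extended signal), a non-negative envelope that peaks at discharges.
3. **Threshold calibration** — per channel, energy peaks are split into
   activated/inactivated groups by exact 1-D 2-means; the detection threshold
   is the mean of the two centroids.  The clustering's silhouette coefficient
   gates quality: channels below the cut-off fall back to a near-maximal
   percentile of their peak values (a channel with no separable activated
   cluster should stay essentially silent rather than fire on noise).
4. **Spatial spike detection** — a sample is a discharge of channel *i* iff
   its energy exceeds the channel threshold *and* is the strict maximum over
   a 3x3 spatial neighbourhood across a centred 5-ms temporal window.  The
   MUAP's fast decay across muscle fibres guarantees such a local peak at
   the electrode nearest the source.

The result is a binary channel x time spike matrix; downstream imaging turns
it into discharge-rate images on the electrode grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .montage import EmgRecording, MontageLayout

__all__ = [
    "DecompositionConfig",
    "DecompositionModel",
    "EnergyEnvelope",
    "SpikeTrainMatrix",
    "fit_whitening",
    "apply_whitening",
    "energy_envelope",
    "two_means_1d",
    "silhouette_1d",
    "calibrate_thresholds",
    "detect_spikes",
    "fit_decomposition",
    "decompose_trial",
    "match_discharges",
    "score_recovery",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DecompositionConfig:
    """Decomposition hyper-parameters.

    ``extension_R`` is the number of delayed samples in the energy sum
    (10 samples ~ 5 ms at 2,048 Hz, the MUAP time scale).  The spatial and
    temporal detection windows are 3x3 electrodes and 5 ms.  ``silhouette_min``
    is the clustering-quality acceptance cut-off; channels below it use the
    ``fallback_percentile`` of their peak values as threshold.
    ``candidate_stat`` selects the quantity maximised in the spatial/temporal
    window: the energy envelope (default) or the absolute whitened amplitude.
    """

    extension_R: int = 10
    spatial_window: tuple = (3, 3)
    temporal_window_ms: float = 5.0
    silhouette_min: float = 0.7
    fallback_percentile: float = 99.9
    min_peaks: int = 10
    eig_floor_rel: float = 1e-12
    candidate_stat: str = "energy"

    def __post_init__(self) -> None:
        if self.extension_R < 1:
            raise ConfigurationError("extension_R must be >= 1")
        if self.spatial_window != (3, 3):
            raise ConfigurationError("only a 3x3 spatial window is supported")
        if self.candidate_stat not in ("energy", "amplitude"):
            raise ConfigurationError("candidate_stat: 'energy' or 'amplitude'")

    def temporal_half_window(self, fs: float) -> int:
        """Half-width in samples of the centred temporal window."""
        return int(np.floor(self.temporal_window_ms / 2.0 * fs / 1000.0))


@dataclass
class EnergyEnvelope:
    """Per-channel sliding energy ``e_i(t)``, shape (channels, time)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be (channels, time)")


@dataclass
class SpikeTrainMatrix:
    """Binary channel x time matrix of detected cumulative discharges."""

    spikes: np.ndarray
    fs: float
    montage: MontageLayout

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 2:
            raise ValueError("spikes must be (channels, time)")

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.spikes.shape[1]

    def channel_times(self, channel: int) -> np.ndarray:
        return np.nonzero(self.spikes[channel])[0]


@dataclass
class DecompositionModel:
    """Fitted decomposition parameters (whitening, thresholds, windows)."""

    whitening: np.ndarray
    thresholds: np.ndarray
    channel_quality: np.ndarray
    low_quality: np.ndarray
    excluded: set
    config: DecompositionConfig = field(default_factory=DecompositionConfig)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")
        if np.any(self.thresholds < 0):
            raise ValueError("thresholds must be non-negative")


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def fit_whitening(calib, eig_floor_rel: float = 1e-12) -> np.ndarray:
    """ZCA whitening matrix ``W = U L^(-1/2) U^T`` of the channel covariance.

    Accepts an :class:`~cwcst.montage.EmgRecording` or a time-major array.
    Channel means are removed before the covariance estimate.  Eigenvalues
    below ``eig_floor_rel`` times the largest are floored (with a warning):
    the covariance is rank-deficient and the corresponding directions carry
    no usable signal.
    """
    X = calib.samples if isinstance(calib, EmgRecording) else np.asarray(calib)
    X = X.astype(np.float64, copy=False)
    Xc = X - X.mean(axis=0, keepdims=True)
    sigma = (Xc.T @ Xc) / max(Xc.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(sigma)
    floor = max(evals.max(), 0.0) * eig_floor_rel
    if floor == 0.0:
        floor = np.finfo(np.float64).tiny
    if np.any(evals < floor):
        warnings.warn(
            "rank-deficient channel covariance; eigenvalues floored",
            stacklevel=2)
        evals = np.maximum(evals, floor)
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T


def apply_whitening(rec, W: np.ndarray) -> np.ndarray:
    """Whitened signals ``Z(t) = W X(t)``, returned time-major (T, C)."""
    X = rec.samples if isinstance(rec, EmgRecording) else np.asarray(rec)
    if X.shape[1] != W.shape[1]:
        raise ValueError(
            f"signal has {X.shape[1]} channels, whitening expects {W.shape[1]}"
        )
    return X @ W.T.astype(X.dtype, copy=False)


# ---------------------------------------------------------------------------
# energy envelope
# ---------------------------------------------------------------------------

def energy_envelope(Z: np.ndarray, R: int, fs: float = 2048.0) -> EnergyEnvelope:
    """Sliding sum of squares over the R most recent samples, per channel.

    ``e_i(t) = sum_{r=1..R} z_i(t - r + 1)^2`` with zero-padded delays for
    ``t < R - 1``.  Input is time-major (T, C); output values are (C, T).
    """
    if R < 1:
        raise ConfigurationError("R must be >= 1")
    Z = np.asarray(Z)
    T, C = Z.shape
    out = np.empty((C, T), dtype=Z.dtype if Z.dtype == np.float64 else np.float32)
    chunk = max(1, int(8e6) // max(T, 1))
    for c0 in range(0, C, chunk):
        z = Z[:, c0:c0 + chunk].astype(np.float64)
        cs = np.cumsum(z * z, axis=0)
        e = cs.copy()
        e[R:] -= cs[:-R]
        out[c0:c0 + chunk] = e.T
    return EnergyEnvelope(values=out, fs=fs)


# ---------------------------------------------------------------------------
# exact 1-D two-means and silhouette
# ---------------------------------------------------------------------------

def two_means_1d(x: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Exact 2-means on scalars: enumerate split points in sorted order.

    For 1-D data the optimal 2-means partition is contiguous in sorted order,
    so scanning all n-1 splits with prefix sums finds the global optimum.
    Returns ``(low_centroid, high_centroid, labels)`` with labels aligned to
    the input order (0 = low cluster).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.cumsum(xs)
    s2 = np.cumsum(xs * xs)
    m = np.arange(1, n)  # low-cluster sizes
    sse_low = s2[m - 1] - s1[m - 1] ** 2 / m
    s1r = s1[-1] - s1[m - 1]
    s2r = s2[-1] - s2[m - 1]
    sse_high = s2r - s1r**2 / (n - m)
    best = int(np.argmin(sse_low + sse_high)) + 1
    c_low = float(s1[best - 1] / best)
    c_high = float((s1[-1] - s1[best - 1]) / (n - best))
    labels = np.empty(n, dtype=np.intp)
    labels[order[:best]] = 0
    labels[order[best:]] = 1
    return c_low, c_high, labels


def silhouette_1d(x: np.ndarray, split: int) -> float:
    """Mean silhouette of a contiguous-in-sorted-order 2-way partition.

    ``split`` is the low-cluster size over the sorted values.  Exact
    O(n log n) evaluation via prefix sums; matches the standard definition
    (singleton clusters score 0).
    """
    xs = np.sort(np.asarray(x, dtype=np.float64), kind="stable")
    n = xs.size
    m = split
    if m < 1 or m >= n:
        raise ValueError("split must leave both clusters non-empty")

    def intra(y: np.ndarray) -> np.ndarray:
        k = y.size
        if k == 1:
            return np.zeros(1)
        cs = np.cumsum(y)
        j = np.arange(k)
        total = (y * j - np.concatenate([[0.0], cs[:-1]])) \
            + ((cs[-1] - cs) - y * (k - 1 - j))
        return total / (k - 1)

    lo, hi = xs[:m], xs[m:]
    a = np.concatenate([intra(lo), intra(hi)])
    # clusters are ordered on the line, so cross-cluster mean distances are
    # distances to the other cluster's mean
    b = np.concatenate([hi.mean() - lo, hi - lo.mean()])
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    if m == 1:
        s[0] = 0.0
    if n - m == 1:
        s[-1] = 0.0
    return float(s.mean())


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def calibrate_thresholds(
    energy: EnergyEnvelope, cfg: DecompositionConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel detection thresholds from calibration energy.

    Candidate peaks are the temporal local maxima of ``e_i(t)`` above the
    channel's median energy.  2-means splits them into activated and
    inactivated groups and the threshold is the centroid mean; the
    clustering silhouette is recorded as channel quality.  Channels whose
    silhouette misses the cut-off, have fewer than ``min_peaks`` peaks, or
    cluster degenerately use the fallback percentile of their peak values and
    are flagged low-quality.  Returns ``(thresholds, silhouettes, low_quality)``.
    """
    cfg = cfg or DecompositionConfig()
    values = energy.values
    n_channels = values.shape[0]
    thresholds = np.zeros(n_channels)
    silhouettes = np.zeros(n_channels)
    low_quality = np.zeros(n_channels, dtype=bool)
    global_max = float(values.max(initial=0.0))
    dead_floor = global_max * 1e-12

    for i in range(n_channels):
        e = np.asarray(values[i], dtype=np.float64)
        e_max = e.max(initial=0.0)
        if e_max <= dead_floor or e_max == 0.0:
            # silent channel: a threshold at the global ceiling never fires
            thresholds[i] = global_max
            low_quality[i] = True
            continue
        peaks, _ = signal.find_peaks(e, height=float(np.median(e)))
        pv = e[peaks]
        if pv.size < cfg.min_peaks:
            warnings.warn(
                f"channel {i}: only {pv.size} calibration peaks; "
                "percentile fallback", stacklevel=2)
            src = pv if pv.size else e
            thresholds[i] = float(np.percentile(src, cfg.fallback_percentile))
            low_quality[i] = True
            continue
        c_low, c_high, labels = two_means_1d(pv)
        if not (c_high > c_low):
            thresholds[i] = float(np.percentile(pv, cfg.fallback_percentile))
            low_quality[i] = True
            continue
        sil = silhouette_1d(pv, int(np.sum(labels == 0)))
        silhouettes[i] = sil
        if sil < cfg.silhouette_min:
            thresholds[i] = float(np.percentile(pv, cfg.fallback_percentile))
            low_quality[i] = True
        else:
            thresholds[i] = 0.5 * (c_low + c_high)
    return thresholds, silhouettes, low_quality


# ---------------------------------------------------------------------------
# spatial spike detection
# ---------------------------------------------------------------------------

def _detect_core(
    energy_values: np.ndarray,
    stat_values: np.ndarray,
    thresholds: np.ndarray,
    montage: MontageLayout,
    half_window: int,
    excluded: set,
) -> np.ndarray:
    """Binary (C, T) spike matrix from the two detection conditions.

    Condition (1): energy exceeds the channel threshold.  Condition (2): the
    candidate statistic is the strict maximum over the 3x3 spatial
    neighbourhood (grid-truncated at edges; wrapped across columns when the
    montage is circular) and the centred temporal window.  Exactly equal
    statistics are resolved deterministically: the lowest channel index,
    then the earliest time, wins.
    """
    C, T = energy_values.shape
    grid = montage.grid_index
    chan_of_cell = grid  # (rows, cols) -> channel index

    stat = np.asarray(stat_values, dtype=np.float32)
    vol = stat[grid]  # (n_rows, n_cols, T)
    if excluded:
        mask = np.zeros(C, dtype=bool)
        mask[list(excluded)] = True
        vol = vol.copy()
        vol[mask[grid]] = -np.inf

    col_mode = "wrap" if montage.circular else "constant"
    mf = ndimage.maximum_filter(
        vol,
        size=(3, 3, 2 * half_window + 1),
        mode=("constant", col_mode, "constant"),
        cval=-np.inf,
    )
    above = energy_values > np.asarray(thresholds)[:, None]  # condition (1)
    cand = (vol >= mf) & above[grid] & np.isfinite(vol)
    del mf, above

    spikes = np.zeros((C, T), dtype=np.uint8)
    rs, cs, ts = np.nonzero(cand)
    n_rows, n_cols = montage.n_rows, montage.n_cols
    for r, c, t in zip(rs.tolist(), cs.tolist(), ts.tolist()):
        center_val = vol[r, c, t]
        center_chan = int(chan_of_cell[r, c])
        win = True
        for dr in (-1, 0, 1):
            rr = r + dr
            if rr < 0 or rr >= n_rows:
                continue
            for dc in (-1, 0, 1):
                cc = c + dc
                if montage.circular:
                    cc %= n_cols
                elif cc < 0 or cc >= n_cols:
                    continue
                lo = max(0, t - half_window)
                hi = min(T, t + half_window + 1)
                seg = vol[rr, cc, lo:hi]
                other_chan = int(chan_of_cell[rr, cc])
                for dt_idx in np.nonzero(seg >= center_val)[0]:
                    s = lo + int(dt_idx)
                    if other_chan == center_chan and s == t:
                        continue
                    v = seg[dt_idx]
                    if v > center_val:
                        win = False
                    elif v == center_val and (other_chan, s) < (center_chan, t):
                        win = False
                    if not win:
                        break
                if not win:
                    break
            if not win:
                break
        if win:
            spikes[center_chan, t] = 1
    return spikes


def detect_spikes(
    energy: EnergyEnvelope,
    model: DecompositionModel,
    montage: MontageLayout,
    stat_values: np.ndarray | None = None,
) -> SpikeTrainMatrix:
    """Apply the two spike conditions to an energy envelope.

    ``stat_values`` overrides the statistic used for the local-maximum
    condition (per ``config.candidate_stat``); the threshold condition always
    uses the energy.
    """
    half = model.config.temporal_half_window(energy.fs)
    stat = energy.values if stat_values is None else stat_values
    spikes = _detect_core(
        energy.values, stat, model.thresholds, montage, half, model.excluded
    )
    return SpikeTrainMatrix(spikes=spikes, fs=energy.fs, montage=montage)


# ---------------------------------------------------------------------------
# fitting and per-trial decomposition
# ---------------------------------------------------------------------------

def _zero_excluded(samples: np.ndarray, excluded: set) -> np.ndarray:
    if not excluded:
        return samples
    out = samples.copy()
    out[:, list(excluded)] = 0
    return out


def fit_decomposition(
    calib: EmgRecording, cfg: DecompositionConfig | None = None
) -> DecompositionModel:
    """Fit whitening and per-channel thresholds on one calibration trial."""
    cfg = cfg or DecompositionConfig()
    X = _zero_excluded(calib.samples, calib.excluded_channels)
    W = fit_whitening(X, eig_floor_rel=cfg.eig_floor_rel)
    Z = apply_whitening(X, W)
    energy = energy_envelope(Z, cfg.extension_R, fs=calib.fs)
    thresholds, sil, lowq = calibrate_thresholds(energy, cfg)
    return DecompositionModel(
        whitening=W,
        thresholds=thresholds,
        channel_quality=sil,
        low_quality=lowq,
        excluded=set(calib.excluded_channels),
        config=cfg,
    )


def decompose_trial(rec: EmgRecording, model: DecompositionModel
                    ) -> SpikeTrainMatrix:
    """Whiten, compute energy, and detect channel-wise cumulative spikes."""
    excluded = set(rec.excluded_channels) | set(model.excluded)
    X = _zero_excluded(rec.samples, excluded)
    Z = apply_whitening(X, model.whitening)
    energy = energy_envelope(Z, model.config.extension_R, fs=rec.fs)
    stat = None
    if model.config.candidate_stat == "amplitude":
        stat = np.abs(Z.T).astype(np.float32)
    half = model.config.temporal_half_window(rec.fs)
    spikes = _detect_core(
        energy.values,
        energy.values if stat is None else stat,
        model.thresholds,
        rec.montage,
        half,
        excluded,
    )
    return SpikeTrainMatrix(spikes=spikes, fs=rec.fs, montage=rec.montage)


# ---------------------------------------------------------------------------
# recovery scoring against ground truth
# ---------------------------------------------------------------------------

def match_discharges(
    true_times: np.ndarray,
    detected_times: np.ndarray,
    tol: int = 2,
    max_lag: int = 40,
) -> tuple[int, int]:
    """Greedy one-to-one matching of detections to planted discharges.

    Detection marks the energy maximum, which trails the discharge onset by a
    constant template-dependent offset, so a single global lag (the rounded
    median of nearest-detection deltas, bounded by ``max_lag``) is removed
    before matching at ``+-tol`` samples.  Returns ``(n_matched, lag)``.
    """
    true_times = np.sort(np.asarray(true_times, dtype=np.int64))
    detected_times = np.sort(np.asarray(detected_times, dtype=np.int64))
    if true_times.size == 0 or detected_times.size == 0:
        return 0, 0
    idx = np.searchsorted(detected_times, true_times)
    deltas = []
    for t, i in zip(true_times, idx):
        cands = []
        if i < detected_times.size:
            cands.append(detected_times[i] - t)
        if i > 0:
            cands.append(detected_times[i - 1] - t)
        d = min(cands, key=abs)
        if abs(d) <= max_lag:
            deltas.append(d)
    lag = int(round(np.median(deltas))) if deltas else 0
    shifted = true_times + lag
    used = np.zeros(detected_times.size, dtype=bool)
    matched = 0
    j = 0
    for t in shifted:
        while j < detected_times.size and detected_times[j] < t - tol:
            j += 1
        for k in range(j, detected_times.size):
            if detected_times[k] > t + tol:
                break
            if not used[k]:
                used[k] = True
                matched += 1
                break
    return matched, lag


def score_recovery(
    truth,
    spikes: SpikeTrainMatrix,
    tol: int = 2,
    max_lag: int = 40,
) -> tuple[float, float]:
    """Recall and precision of channel-assigned discharges.

    For every motor unit, planted discharges at its centre channel are
    matched (at ``+-tol`` samples after constant-lag removal) against the
    detections pooled over the centre's 3x3 grid neighbourhood.  Recall and
    precision aggregate matched counts over all units.
    """
    montage = spikes.montage
    grid = montage.grid_index
    n_true = n_det = n_match = 0
    for mu in range(truth.spike_trains.shape[0]):
        tt = truth.mu_spike_times(mu)
        if tt.size == 0:
            continue
        ch = int(truth.center_channels[mu])
        r0, c0 = montage.channel_to_grid(ch)
        det = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = r0 + dr, c0 + dc
                if montage.circular:
                    c %= montage.n_cols
                if 0 <= r < montage.n_rows and 0 <= c < montage.n_cols:
                    det.append(spikes.channel_times(int(grid[r, c])))
        det = np.unique(np.concatenate(det)) if det else np.array([], dtype=int)
        m, _ = match_discharges(tt, det, tol=tol, max_lag=max_lag)
        n_true += tt.size
        n_det += det.size
        n_match += m
    recall = n_match / n_true if n_true else 0.0
    precision = n_match / n_det if n_det else 0.0
    return recall, precision
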