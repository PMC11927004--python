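"""Whitening, energy, threshold calibration, and spatial spike detection."""

import numpy as np
import pytest

from cwcst.decompose import (
    DecompositionConfig,
    DecompositionModel,
    EnergyEnvelope,
    _detect_core,
    apply_whitening,
    calibrate_thresholds,
    detect_spikes,
    energy_envelope,
    fit_whitening,
    match_discharges,
    silhouette_1d,
    two_means_1d,
)
from cwcst.montage import MontageLayout


def brute_force_detect(energy, thresholds, montage, half_window):
    """Exhaustive evaluation of the two spike conditions with the
    deterministic (channel, time) tie-break — the independent oracle."""
    C, T = energy.shape
    spikes = np.zeros((C, T), dtype=np.uint8)
    grid = montage.grid_index
    for ch in range(C):
        r0, c0 = montage.channel_to_grid(ch)
        for t in range(T):
            v = energy[ch, t]
            if not v > thresholds[ch]:
                continue
            win = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r, c = r0 + dr, c0 + dc
                    if montage.circular:
                        c %= montage.n_cols
                    if not (0 <= r < montage.n_rows and 0 <= c < montage.n_cols):
                        continue
                    oc = int(grid[r, c])
                    for s in range(max(0, t - half_window),
                                   min(T, t + half_window + 1)):
                        if oc == ch and s == t:
                            continue
                        w = energy[oc, s]
                        if w > v or (w == v and (oc, s) < (ch, t)):
                            win = False
                            break
                    if not win:
                        break
                if not win:
                    break
            if win:
                spikes[ch, t] = 1
    return spikes


class TestWhitening:
    def test_diagonal_closed_form(self):
        # four points with sample covariance exactly 2I -> W = I / sqrt(2)
        a = np.sqrt(1.5)
        X = np.array([[a, a], [a, -a], [-a, a], [-a, -a]])
        W = fit_whitening(X)
        assert np.allclose(W, np.eye(2) / np.sqrt(2), atol=1e-12)

    def test_whitened_covariance_is_identity(self, rng):
        X = rng.standard_normal((4000, 8)) @ rng.standard_normal((8, 8))
        W = fit_whitening(X)
        Z = apply_whitening(X, W)
        Zc = Z - Z.mean(axis=0)
        cov = Zc.T @ Zc / (len(Zc) - 1)
        assert np.abs(cov - np.eye(8)).max() < 1e-6

    def test_already_white_input_gives_identity(self, rng):
        X = rng.standard_normal((4000, 6))
        Z = apply_whitening(X, fit_whitening(X))
        W2 = fit_whitening(Z)
        assert np.allclose(W2, np.eye(6), atol=1e-6)

    def test_rank_deficient_covariance_warns(self, rng):
        x = rng.standard_normal((500, 1))
        X = np.hstack([x, x, rng.standard_normal((500, 1))])
        with pytest.warns(UserWarning, match="rank-deficient"):
            W = fit_whitening(X)
        assert np.all(np.isfinite(W))

    def test_apply_is_plain_matrix_product(self, rng):
        X = rng.standard_normal((5, 3))
        W = rng.standard_normal((3, 3))
        expect = np.stack([W @ X[t] for t in range(5)])
        assert np.allclose(apply_whitening(X, W), expect, atol=1e-12)
        assert np.allclose(apply_whitening(2.5 * X, W),
                           2.5 * apply_whitening(X, W), atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            apply_whitening(rng.standard_normal((10, 4)), np.eye(3))


class TestEnergyEnvelope:
    def test_constant_signal_closed_form(self):
        Z = np.ones((50, 1))
        e = energy_envelope(Z, R=10).values[0]
        assert np.allclose(e[9:], 10.0)
        assert np.allclose(e[:9], np.arange(1, 10))  # zero-padded delays

    def test_zero_signal(self):
        assert np.all(energy_envelope(np.zeros((30, 2)), R=4).values == 0)

    def test_matches_brute_force_sliding_sum(self, rng):
        Z = rng.standard_normal((40, 1))
        R = 4
        e = energy_envelope(Z, R).values[0]
        for t in range(40):
            expect = sum(Z[t - r + 1, 0] ** 2 for r in range(1, R + 1)
                         if t - r + 1 >= 0)
            assert e[t] == pytest.approx(expect, rel=1e-6)


class TestTwoMeansAndSilhouette:
    def test_centroid_mean_rule(self):
        lo, hi, labels = two_means_1d(np.array([1.0, 2.0, 9.0, 10.0]))
        assert (lo, hi) == (1.5, 9.5)
        assert 0.5 * (lo + hi) == 5.5
        assert labels.tolist() == [0, 0, 1, 1]

    def test_split_is_globally_optimal(self, rng):
        from sklearn.cluster import KMeans
        for _ in range(10):
            x = rng.standard_normal(60) + 3 * rng.integers(0, 2, 60)
            lo, hi, labels = two_means_1d(x)
            sse = np.sum((x[labels == 0] - lo) ** 2) \
                + np.sum((x[labels == 1] - hi) ** 2)
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
                x.reshape(-1, 1))
            assert sse <= km.inertia_ + 1e-9

    def test_silhouette_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score
        for _ in range(10):
            x = np.concatenate([rng.normal(0, 1, 40), rng.normal(6, 1, 30)])
            _, _, labels = two_means_1d(x)
            split = int(np.sum(labels == 0))
            ours = silhouette_1d(x, split)
            xs = np.sort(x)
            ref_labels = np.concatenate([np.zeros(split), np.ones(len(x) - split)])
            ref = silhouette_score(xs.reshape(-1, 1), ref_labels)
            assert ours == pytest.approx(ref, abs=1e-9)


class TestCalibrateThresholds:
    def _envelope_from_peaks(self, peak_values):
        # energy trace whose temporal local maxima are exactly peak_values
        e = np.zeros(3 * len(peak_values) + 1)
        e[1::3] = peak_values
        return EnergyEnvelope(values=e[None, :], fs=2048.0)

    def test_bimodal_peaks_give_between_mode_threshold(self, rng):
        peaks = np.concatenate([rng.normal(1, 0.1, 40), rng.normal(9, 0.1, 40)])
        peaks = np.abs(peaks)
        lam, sil, lowq = calibrate_thresholds(self._envelope_from_peaks(peaks))
        assert 2.0 < lam[0] < 8.0
        assert sil[0] > 0.7
        assert not lowq[0]

    def test_identical_peaks_fall_back(self):
        lam, sil, lowq = calibrate_thresholds(
            self._envelope_from_peaks(np.full(30, 4.0)))
        assert lowq[0]
        assert lam[0] == pytest.approx(4.0)

    def test_too_few_peaks_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="fallback"):
            lam, sil, lowq = calibrate_thresholds(
                self._envelope_from_peaks(np.array([1.0, 5.0, 2.0])))
        assert lowq[0]

    def test_silent_channel_never_fires(self):
        values = np.vstack([np.zeros(100), np.abs(np.sin(np.arange(100.0)))])
        lam, sil, lowq = calibrate_thresholds(
            EnergyEnvelope(values=values, fs=2048.0))
        assert lowq[0]
        assert np.all(values[0] <= lam[0])


class TestDetectSpikes:
    def _model(self, thresholds, cfg=None):
        cfg = cfg or DecompositionConfig()
        n = len(thresholds)
        return DecompositionModel(
            whitening=np.eye(n), thresholds=np.asarray(thresholds, float),
            channel_quality=np.ones(n), low_quality=np.zeros(n, bool),
            excluded=set(), config=cfg,
        )

    def test_zero_energy_no_spikes(self):
        m = MontageLayout.regular_grid(2, 3)
        env = EnergyEnvelope(np.zeros((6, 50)), fs=2048.0)
        out = detect_spikes(env, self._model(np.full(6, 0.5)), m)
        assert out.spikes.sum() == 0

    def test_single_isolated_peak(self):
        m = MontageLayout.regular_grid(2, 3)
        e = np.zeros((6, 50))
        e[4, 20] = 3.0
        out = detect_spikes(EnergyEnvelope(e, fs=2048.0),
                            self._model(np.full(6, 1.0)), m)
        assert out.spikes.sum() == 1
        assert out.spikes[4, 20] == 1

    def test_exact_tie_resolved_to_lowest_channel_then_time(self):
        m = MontageLayout.regular_grid(1, 3)
        e = np.zeros((3, 30))
        e[0, 10] = e[1, 12] = 2.0  # same spatial window, same temporal window
        spikes = _detect_core(e, e, np.full(3, 1.0), m, half_window=5,
                              excluded=set())
        assert spikes[0, 10] == 1 and spikes[1, 12] == 0
        e2 = np.zeros((3, 30))
        e2[1, 8] = e2[1, 11] = 2.0  # same channel, earliest time wins
        spikes2 = _detect_core(e2, e2, np.full(3, 1.0), m, half_window=5,
                               excluded=set())
        assert spikes2[1, 8] == 1 and spikes2[1, 11] == 0

    def test_excluded_channels_never_spike_nor_suppress(self):
        m = MontageLayout.regular_grid(1, 3)
        e = np.zeros((3, 20))
        e[1, 10] = 5.0   # excluded channel with the largest energy
        e[0, 10] = 2.0
        spikes = _detect_core(e, e, np.full(3, 1.0), m, half_window=2,
                              excluded={1})
        assert spikes[1].sum() == 0
        assert spikes[0, 10] == 1

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_brute_force_on_random_instances(self, circular):
        rng = np.random.default_rng(77)
        for _ in range(15):
            n_rows = int(rng.integers(2, 5))
            n_cols = int(rng.integers(2, 9))
            T = 120
            m = MontageLayout.regular_grid(n_rows, n_cols, circular=circular)
            e = rng.random((m.n_channels, T)).astype(np.float32)
            lam = np.quantile(e, 0.8, axis=1)
            half = int(rng.integers(1, 6))
            got = _detect_core(e, e, lam, m, half_window=half, excluded=set())
            want = brute_force_detect(e.astype(np.float64), lam, m, half)
            assert np.array_equal(got, want)

    def test_within_channel_spikes_separated(self, rng):
        m = MontageLayout.regular_grid(2, 4)
        e = rng.random((8, 300)).astype(np.float32)
        half = 5
        spikes = _detect_core(e, e, np.quantile(e, 0.5, axis=1), m,
                              half_window=half, excluded=set())
        for ch in range(8):
            times = np.nonzero(spikes[ch])[0]
            if len(times) > 1:
                assert np.diff(times).min() > half


class TestNoiseFloor:
    def test_rest_period_spike_density_below_one_hz_per_channel(self):
        """With thresholds calibrated on data containing activity and rest,
        the silent rest period yields almost no detections."""
        import warnings

        from cwcst.decompose import decompose_trial, fit_decomposition
        from cwcst.montage import default_montage
        from cwcst.preprocess import preprocess
        from cwcst.simulate import (
            MotorUnitSpec,
            MuapTemplate,
            SimulationConfig,
            synthesize_trial,
        )

        rng = np.random.default_rng(3)
        mus = [
            MotorUnitSpec(MuapTemplate(20, (int(r), int(c))),
                          mean_rate=10.0, isi_cv=0.15, recruitment={"M1"})
            for r, c in [(1, 2), (4, 6), (6, 10), (2, 14), (5, 19)]
        ]
        cfg = SimulationConfig(
            motor_units=mus, noise_sd=0.05, motion_duration_s=6.0,
            rest_duration_s=4.0, gesture_ids=("M1", "M10"),
            trial_gain_jitter=0.0, rate_jitter=0.0,
            montage=default_montage(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, _ = synthesize_trial(cfg, ["M1"], rng)
            clean = preprocess(rec)
            model = fit_decomposition(clean)
            spikes = decompose_trial(clean, model)
        rest_start = int(6.0 * cfg.fs)
        rest = spikes.spikes[:, rest_start:]
        density = rest.sum() / (rest.shape[1] / cfg.fs) / rest.shape[0]
        assert density < 1.0


class TestMatching:
    def test_constant_lag_is_removed(self):
        true = np.array([100, 300, 500, 700])
        det = true + 13
        matched, lag = match_discharges(true, det, tol=2)
        assert matched == 4 and lag == 13

    def test_unmatched_spikes_counted_once(self):
        true = np.array([100, 200])
        det = np.array([100, 101, 200])  # double detection
        matched, _ = match_discharges(true, det, tol=2)
        assert matched == 2
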