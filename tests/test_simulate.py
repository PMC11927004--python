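"""Synthetic generator: spike statistics, convolution, protocol timing."""

import warnings

import numpy as np
import pytest

from cwcst.montage import MontageLayout, default_montage
from cwcst.simulate import (
    ConfigurationError,
    MotorUnitSpec,
    MuapTemplate,
    SimulationConfig,
    default_simulation,
    generate_session,
    generate_spike_train,
    noise_sd_for_snr,
    synthesize_trial,
)

FS = 2048.0


def _mu(center=(2, 2), rate=10.0, cv=0.0, amplitude=1.0, gestures=("M1",)):
    return MotorUnitSpec(
        template=MuapTemplate(20, center, amplitude=amplitude),
        mean_rate=rate, isi_cv=cv, recruitment=set(gestures),
    )


class TestSpikeTrains:
    def test_zero_jitter_gives_uniform_comb(self, rng):
        train = generate_spike_train(_mu(cv=0.0), 10.0, FS, rng)
        times = np.nonzero(train)[0]
        # first spike one full ISI in; spikes at k * 0.1 s, so ~100 of them
        # (boundary rounding decides whether the spike at t = 10 s lands)
        assert len(times) in (99, 100)
        isis = np.diff(times)
        assert isis.min() >= 204 and isis.max() <= 205

    def test_mean_count_matches_renewal_theory(self):
        # renewal process with mean ISI 0.1 s starting one ISI in: the
        # expected count over 10 s is ~99; jitter is zero-mean so the
        # Monte-Carlo mean must sit within 3 SE of it
        counts = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            counts.append(generate_spike_train(_mu(cv=0.2), 10.0, FS, r).sum())
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 99.0) <= 3 * max(se, 1e-9)

    def test_short_duration_may_be_empty(self, rng):
        train = generate_spike_train(_mu(rate=1.0), 0.05, FS, rng)
        assert train.sum() == 0

    def test_rate_violating_refractory_floor_raises(self, rng):
        with pytest.raises(ConfigurationError):
            generate_spike_train(_mu(rate=200.0), 1.0, FS, rng)


def _cfg(mus, **kw):
    defaults = dict(noise_sd=0.0, motion_duration_s=1.5, rest_duration_s=0.5,
                    gesture_ids=("M1", "M2", "M10"),
                    trial_gain_jitter=0.0, rate_jitter=0.0,
                    montage=MontageLayout.regular_grid(6, 8))
    defaults.update(kw)
    return SimulationConfig(motor_units=mus, **defaults)


class TestSynthesis:
    def test_noise_only_trial_has_unit_sd(self, rng):
        cfg = _cfg([], noise_sd=1.0)
        rec, truth = synthesize_trial(cfg, ["M1"], rng)
        sd = rec.samples.std(axis=0)
        assert np.allclose(sd, 1.0, atol=0.05)
        assert truth.spike_trains.nnz == 0

    def test_single_spike_matches_template_convolution(self, rng):
        # 1.5-s motion at 0.65 Hz with zero jitter -> exactly one discharge
        mu = _mu(center=(3, 4), rate=1.0 / 1.2, cv=0.0, amplitude=1.3)
        cfg = _cfg([mu])
        rec, truth = synthesize_trial(cfg, ["M1"], rng)
        t0 = truth.mu_spike_times(0)
        assert len(t0) == 1
        t0 = t0[0]
        center_ch = int(truth.center_channels[0])
        L = mu.template.length_samples
        got = rec.samples[t0:t0 + L, center_ch]
        assert np.allclose(got, 1.3 * mu.template.waveform, atol=1e-5)
        # cross-fibre (column) peak-to-peak decays monotonically
        grid = cfg.montage.grid_index
        p2p = [np.ptp(rec.samples[:, grid[3, c]]) for c in range(4, 8)]
        assert all(a > b for a, b in zip(p2p, p2p[1:]))

    def test_mixture_is_linear_in_motor_units(self, rng):
        mu_a = _mu(center=(1, 1), rate=7.0, cv=0.0)
        mu_b = _mu(center=(4, 6), rate=9.0, cv=0.0, gestures=("M2",))
        seq = ["M1", "M2"]
        rec_ab, _ = synthesize_trial(_cfg([mu_a, mu_b]), seq, rng)
        rec_a, _ = synthesize_trial(_cfg([mu_a]), seq, rng)
        rec_b, _ = synthesize_trial(_cfg([mu_b]), seq, rng)
        assert np.allclose(rec_ab.samples, rec_a.samples + rec_b.samples,
                           atol=1e-6)

    def test_rest_recruits_nothing(self, rng):
        cfg = _cfg([_mu()])
        rec, truth = synthesize_trial(cfg, ["M2", "M10"], rng)
        assert truth.spike_trains.nnz == 0
        assert np.all(rec.samples == 0)

    def test_rest_recruitment_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg([_mu(gestures=("M10",))])


class TestProtocol:
    def test_default_trial_lasts_150_seconds(self, rng):
        # 10 gestures x (10-s motion + 5-s rest)
        cfg = default_simulation(seed=3, n_per_gesture=2)
        order = cfg.active_gestures + [cfg.rest_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, _ = synthesize_trial(cfg, order, rng)
        assert rec.duration == pytest.approx(150.0)
        motion_time = sum(b - a for a, b, g in rec.labels if g != "M10")
        rest_time = sum(b - a for a, b, g in rec.labels if g == "M10")
        assert motion_time == pytest.approx(90.0)
        assert rest_time == pytest.approx(60.0)

    def test_session_structure_and_roles(self, mini_session):
        cfg, session, truths = mini_session
        assert len(session.trials) == cfg.n_trials
        assert session.roles.count("calibration") == 1
        for rec in session.trials:
            gestures = [g for _, _, g in rec.labels if g != cfg.rest_id]
            assert sorted(gestures) == sorted(cfg.active_gestures)
            assert rec.labels[-1][2] == cfg.rest_id  # rest performed last

    def test_same_seed_reproduces_session_exactly(self):
        cfg = default_simulation(seed=42, n_per_gesture=2,
                                 motion_duration_s=0.8, rest_duration_s=0.4,
                                 n_trials=2,
                                 montage=MontageLayout.regular_grid(4, 9),
                                 gesture_ids=("M1", "M2", "M3", "M10"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, t1 = generate_session(cfg)
            s2, t2 = generate_session(cfg)
        for a, b in zip(s1.trials, s2.trials):
            assert np.array_equal(a.samples, b.samples)
            assert a.labels == b.labels
        for x, y in zip(t1, t2):
            assert (x.spike_trains != y.spike_trains).nnz == 0


class TestSnrHelper:
    def test_noise_sd_for_snr_closed_form(self):
        clean = np.zeros((100, 2))
        clean[:50] = 2.0  # active power 4
        assert noise_sd_for_snr(clean, 0.0) == pytest.approx(2.0)
        assert noise_sd_for_snr(clean, 20.0) == pytest.approx(0.2)
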