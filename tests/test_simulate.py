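"""Simulator: state process, EEG synthesis, telemetry, reproducibility."""

import math

import numpy as np
import pytest
from scipy import signal as sp_signal

from eegvigil import (SimulationConfig, apply_alert_response,
                      sample_state_path, simulate_session, synthesize_eeg,
                      synthesize_telemetry)
from eegvigil.simulate import ATTENTION, INATTENTION


def _cfg(**kw):
    base = dict(duration_s=60.0, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_nonintegral_hop(self):
        with pytest.raises(ValueError, match="multiple"):
            _cfg(raw_rate=100, frame_rate=6)

    def test_rejects_theta_gain_below_one(self):
        with pytest.raises(ValueError, match="theta_gain"):
            _cfg(theta_gain=0.5)

    def test_rejects_inverted_telemetry_sds(self):
        with pytest.raises(ValueError, match="SDs"):
            _cfg(telemetry_noise_sd={"attention": (5.0, 1.0),
                                     "inattention": (4.0, 5.0)})

    @pytest.mark.parametrize("bad", [0.0, -10.0])
    def test_rejects_nonpositive_duration(self, bad):
        with pytest.raises(ValueError, match="duration"):
            _cfg(duration_s=bad)

    def test_rejects_nonpositive_dwell(self):
        with pytest.raises(ValueError, match="dwell"):
            _cfg(state_dwell_mean_s={"attention": 0.0, "inattention": 25.0})


class TestStatePath:
    def test_infinite_attention_dwell_freezes_state(self):
        cfg = _cfg(state_dwell_mean_s={"attention": math.inf,
                                       "inattention": 5.0})
        path = sample_state_path(cfg, seed=0, start_state=ATTENTION)
        assert np.all(path == ATTENTION)

    def test_same_seed_same_path(self):
        cfg = _cfg(duration_s=300)
        a = sample_state_path(cfg, seed=42)
        b = sample_state_path(cfg, seed=42)
        assert np.array_equal(a, b)

    def test_long_run_inattention_fraction_matches_dwell_ratio(self):
        # alternating renewal with means (60 s, 20 s) -> 25% inattention
        cfg = _cfg(duration_s=600,
                   state_dwell_mean_s={"attention": 60.0, "inattention": 20.0})
        fracs = [sample_state_path(cfg, seed=s).mean() for s in range(25)]
        assert abs(np.mean(fracs) - 0.25) < 0.05

    def test_path_length_and_values(self):
        cfg = _cfg(duration_s=100)
        path = sample_state_path(cfg, seed=1)
        assert path.shape == (600,)
        assert set(np.unique(path)) <= {ATTENTION, INATTENTION}


class TestSynthesizeEEG:
    def test_shapes_and_units(self):
        cfg = _cfg()
        path = sample_state_path(cfg, seed=0)
        rec = synthesize_eeg(path, cfg, seed=0)
        assert rec.data.shape == (cfg.n_raw, 14)
        assert rec.sample_rate == 120

    def test_zero_amplitudes_give_zero_record(self):
        cfg = _cfg(band_amplitude_uv={b: 0.0 for b in
                                      ("delta", "theta", "alpha", "beta")},
                   noise_sd_uv=0.0)
        path = sample_state_path(cfg, seed=0)
        rec = synthesize_eeg(path, cfg, seed=0)
        assert np.all(rec.data == 0.0)

    def test_theta_gain_elevates_theta_envelope_in_every_channel(self):
        # band-pass + Hilbert envelope per state: construction guarantees
        # the inattention theta envelope is larger, channel by channel
        cfg = _cfg(duration_s=600, theta_gain=3.0, seed=3,
                   state_dwell_mean_s={"attention": 60.0, "inattention": 30.0})
        path = sample_state_path(cfg, seed=3)
        rec = synthesize_eeg(path, cfg, seed=3)
        sos = sp_signal.butter(4, [4, 8], btype="bandpass", fs=120,
                               output="sos")
        theta = sp_signal.sosfiltfilt(sos, rec.data, axis=0)
        env = np.abs(sp_signal.hilbert(theta, axis=0))
        mask = path[np.arange(cfg.n_raw) // cfg.hop] == INATTENTION
        assert mask.any() and (~mask).any()
        gap = env[mask].mean(axis=0) - env[~mask].mean(axis=0)
        assert np.all(gap > 0)

    def test_unit_gain_leaves_theta_power_flat(self):
        cfg = _cfg(duration_s=600, theta_gain=1.0, seed=5,
                   state_dwell_mean_s={"attention": 60.0, "inattention": 30.0})
        path = sample_state_path(cfg, seed=5)
        rec = synthesize_eeg(path, cfg, seed=5)
        sos = sp_signal.butter(4, [4, 8], btype="bandpass", fs=120,
                               output="sos")
        theta = sp_signal.sosfiltfilt(sos, rec.data[:, 0])
        mask = path[np.arange(cfg.n_raw) // cfg.hop] == INATTENTION
        ratio = theta[mask].var() / theta[~mask].var()
        assert 0.8 < ratio < 1.25

    def test_reproducible(self):
        cfg = _cfg()
        path = sample_state_path(cfg, seed=0)
        a = synthesize_eeg(path, cfg, seed=9).data
        b = synthesize_eeg(path, cfg, seed=9).data
        assert np.array_equal(a, b)


class TestSynthesizeTelemetry:
    def test_noiseless_trace_is_constant_at_targets(self):
        cfg = _cfg()
        cfg.telemetry_noise_sd = {"attention": (0.0, 0.0),
                                  "inattention": (0.0, 0.0)}
        path = sample_state_path(cfg, seed=0)
        trace = synthesize_telemetry(path, cfg, seed=0)
        assert np.allclose(trace.altitude_ft, 6500.0)
        assert np.allclose(trace.velocity_kn, 250.0)

    def test_inattention_windows_have_larger_variance(self):
        # pure-state 60-frame windows; F-type comparison over replicates
        wins = 0
        hits = 0
        for seed in range(20):
            cfg = _cfg(duration_s=20, telemetry_tau_s=2.0,
                       telemetry_noise_sd={"attention": (1.0, 1.0),
                                           "inattention": (10.0, 10.0)})
            att = synthesize_telemetry(np.zeros(120, dtype=np.int8), cfg,
                                       seed=seed)
            ina = synthesize_telemetry(np.ones(120, dtype=np.int8), cfg,
                                       seed=seed + 1000)
            for s in (0, 60):
                wins += 1
                hits += (np.var(ina.altitude_ft[s:s + 60])
                         > np.var(att.altitude_ft[s:s + 60]))
        assert hits / wins >= 0.95

    def test_reproducible(self):
        cfg = _cfg()
        path = sample_state_path(cfg, seed=0)
        a = synthesize_telemetry(path, cfg, seed=4)
        b = synthesize_telemetry(path, cfg, seed=4)
        assert np.array_equal(a.altitude_ft, b.altitude_ft)
        assert np.array_equal(a.velocity_kn, b.velocity_kn)


class TestSession:
    def test_aligned_lengths(self, short_session):
        cfg, session = short_session
        t = cfg.n_frames
        assert len(session.true_state) == t == session.telemetry.n_frames
        assert session.raw_eeg.n_samples == cfg.n_raw

    def test_session_reproducible(self):
        cfg = _cfg(duration_s=30)
        a = simulate_session(cfg, seed=7)
        b = simulate_session(cfg, seed=7)
        assert np.array_equal(a.raw_eeg.data, b.raw_eeg.data)
        assert np.array_equal(a.true_state, b.true_state)


class TestAlertResponse:
    def test_truncates_long_episodes(self):
        path = np.array([0, 0, 1, 1, 1, 1, 1, 0, 1, 1], dtype=np.int8)
        out = apply_alert_response(path, detect_delay_frames=1,
                                   response_latency_frames=1)
        assert list(out) == [0, 0, 1, 1, 0, 0, 0, 0, 1, 1]

    def test_short_episodes_untouched(self):
        path = np.array([0, 1, 0, 1, 0], dtype=np.int8)
        out = apply_alert_response(path, 2, 2)
        assert np.array_equal(out, path)

    def test_rejects_negative_delay(self):
        with pytest.raises(ValueError):
            apply_alert_response(np.zeros(5, dtype=np.int8), -1, 0)
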