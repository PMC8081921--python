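"""Generator behavior: state structure, event statistics, rendering fidelity,
unit simulation, and determinism."""

import numpy as np
import pytest

from ticstate import synth
from ticstate.core import ValidationError, state_mask
from conftest import small_config


def flat_session_params(cfg: synth.ScenarioConfig) -> dict:
    """Session parameters with all across-session jitter switched off."""
    lfp_rate = {lbl: v / 60.0 for lbl, v in cfg.lfp_rate_per_min.items()}
    resid = {lbl: max(0.0, cfg.tic_rate_per_min.get(lbl, 0.0) / 60.0
                      - cfg.pairing_prob.get(lbl, 0.0) * lfp_rate.get(lbl, 0.0))
             for lbl in cfg.tic_rate_per_min}
    return {
        "lfp_rate_per_s": lfp_rate,
        "tic_residual_rate_per_s": resid,
        "tic_amp_mean": dict(cfg.tic_amp_mean),
        "lfp_amp_mean": dict(cfg.lfp_p2p_mean),
        "rate_factor_wake": 1.0, "rate_factor_sleep": 1.0,
        "amp_gain_tic": 1.0, "amp_gain_lfp": 1.0,
    }


class TestStateSequence:
    def test_fragmentation_disabled_gives_three_segments(self):
        cfg = small_config(n_awakenings=0, transition_micro_s=0.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(0))
        assert len(states.intervals) == 3
        assert [iv[2] for iv in states.intervals] == \
            ["quiet_waking", "transition", "sleep"]

    def test_awakenings_reduce_sleep_label_total(self):
        cfg = small_config(sleep_s=600.0, n_awakenings=2, awakening_s=10.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(1))
        assert states.duration_of("sleep") == pytest.approx(580.0, abs=1e-6)
        assert states.duration_of("other") == pytest.approx(20.0, abs=1e-6)

    def test_transition_total_matches_config(self):
        cfg = synth.paper_default()
        states = synth.generate_state_sequence(cfg, np.random.default_rng(2))
        assert states.duration_of("transition") == pytest.approx(cfg.transition_s)

    def test_zero_length_scenario_rejected(self):
        cfg = small_config(quiet_s=0.0, transition_s=0.0, sleep_s=0.0)
        with pytest.raises(ValidationError):
            synth.generate_state_sequence(cfg, np.random.default_rng(0))


class TestGenerateEvents:
    def test_zero_rates_give_no_events(self):
        cfg = small_config()
        cfg.lfp_rate_per_min = {k: 0.0 for k in cfg.lfp_rate_per_min}
        cfg.tic_rate_per_min = {k: 0.0 for k in cfg.tic_rate_per_min}
        cfg.sleep_tic_session_prob = 0.0
        states = synth.generate_state_sequence(cfg, np.random.default_rng(0))
        truth = synth.generate_events(states, cfg, np.random.default_rng(0))
        assert truth.lfp_onset_s.size == 0 and truth.tic_onset_s.size == 0

    def test_full_pairing_equates_counts(self):
        # pairing 1 everywhere, no residual tics, no sleep block
        cfg = small_config(sleep_s=0.0, n_awakenings=0)
        cfg.pairing_prob = {k: 1.0 for k in cfg.pairing_prob}
        cfg.tic_rate_per_min = {k: 0.0 for k in cfg.tic_rate_per_min}
        states = synth.generate_state_sequence(cfg, np.random.default_rng(3))
        truth = synth.generate_events(states, cfg, np.random.default_rng(3))
        assert truth.tic_onset_s.size == truth.lfp_onset_s.size
        assert (truth.tic_lfp_index >= 0).all()

    def test_quiet_event_count_within_poisson_bound(self):
        cfg = small_config(quiet_s=600.0, transition_s=0.0, sleep_s=0.0,
                           n_awakenings=0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(4))
        truth = synth.generate_events(states, cfg, np.random.default_rng(4),
                                      session_params=flat_session_params(cfg))
        expected = 68.0 / 60.0 * 600.0
        assert abs(truth.lfp_onset_s.size - expected) < 3 * np.sqrt(expected)

    def test_pairing_map_injective_and_lag(self):
        cfg = small_config()
        states = synth.generate_state_sequence(cfg, np.random.default_rng(5))
        truth = synth.generate_events(states, cfg, np.random.default_rng(5))
        paired = truth.tic_lfp_index >= 0
        idx = truth.tic_lfp_index[paired]
        assert np.unique(idx).size == idx.size
        lags = truth.tic_onset_s[paired] - truth.lfp_onset_s[idx]
        np.testing.assert_allclose(lags, cfg.tic_lag_s, atol=2e-3)

    def test_transition_amplitude_cv_elevated_by_decay(self):
        cfg = small_config(transition_s=240.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(6))
        truth = synth.generate_events(states, cfg, np.random.default_rng(6),
                                      session_params=flat_session_params(cfg))
        m = truth.tic_state == "transition"
        amps = truth.tic_p2p[m]
        cv = amps.std(ddof=1) / amps.mean()
        assert cv > 0.6  # decay pushes the CV well above the quiet 0.45


class TestRenderGyro:
    def test_no_tics_noise_only(self):
        cfg = small_config(quiet_s=30.0, transition_s=0.0, sleep_s=30.0)
        cfg.tic_rate_per_min = {k: 0.0 for k in cfg.tic_rate_per_min}
        cfg.pairing_prob = {k: 0.0 for k in cfg.pairing_prob}
        cfg.sleep_tic_session_prob = 0.0
        states = synth.generate_state_sequence(cfg, np.random.default_rng(7))
        truth = synth.generate_events(states, cfg, np.random.default_rng(7))
        gyro = synth.render_gyro(truth, states, cfg, np.random.default_rng(7))
        assert np.abs(gyro[:, 0]).max() < 6 * cfg.gyro_noise_sd * 1.5

    def test_single_tic_noiseless_p2p_exact(self):
        cfg = small_config(gyro_noise_sd=0.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(8))
        truth = synth.GroundTruth(
            lfp_onset_s=np.empty(0), lfp_p2p=np.empty(0),
            lfp_state=np.empty(0, dtype=object),
            tic_onset_s=np.array([10.0]), tic_p2p=np.array([73.5]),
            tic_state=np.array(["quiet_waking"], dtype=object),
            tic_lfp_index=np.array([-1]))
        gyro = synth.render_gyro(truth, states, cfg, np.random.default_rng(8))
        assert gyro[:, 0].max() - gyro[:, 0].min() == pytest.approx(73.5, abs=1e-12)
        assert np.all(gyro[:, 1] == 0) and np.all(gyro[:, 2] == 0)

    def test_overlapping_tics_superpose_linearly(self):
        cfg = small_config(gyro_noise_sd=0.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(9))

        def render(onsets, amps):
            truth = synth.GroundTruth(
                lfp_onset_s=np.empty(0), lfp_p2p=np.empty(0),
                lfp_state=np.empty(0, dtype=object),
                tic_onset_s=np.asarray(onsets), tic_p2p=np.asarray(amps),
                tic_state=np.array(["quiet_waking"] * len(onsets), dtype=object),
                tic_lfp_index=np.full(len(onsets), -1))
            return synth.render_gyro(truth, states, cfg, np.random.default_rng(9))

        both = render([10.0, 10.1], [50.0, 80.0])
        first = render([10.0], [50.0])
        second = render([10.1], [80.0])
        np.testing.assert_allclose(both[:, 0], first[:, 0] + second[:, 0],
                                   atol=1e-12)

    def test_kernel_longer_than_session_rejected(self):
        cfg = small_config(quiet_s=0.2, transition_s=0.0, sleep_s=0.0,
                           n_awakenings=0, gyro_kernel_s=0.35)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(0))
        truth = synth.generate_events(states, cfg, np.random.default_rng(0))
        with pytest.raises(ValidationError, match="kernel"):
            synth.render_gyro(truth, states, cfg, np.random.default_rng(0))


class TestRenderLfpAndWideband:
    def test_single_lfp_spike_noiseless_p2p_exact(self):
        cfg = small_config(lfp_noise_sd=0.0)
        states = synth.generate_state_sequence(cfg, np.random.default_rng(1))
        truth = synth.GroundTruth(
            lfp_onset_s=np.array([20.0]), lfp_p2p=np.array([987.0]),
            lfp_state=np.array(["quiet_waking"], dtype=object),
            tic_onset_s=np.empty(0), tic_p2p=np.empty(0),
            tic_state=np.empty(0, dtype=object), tic_lfp_index=np.empty(0, int))
        lfp = synth.render_lfp(truth, states, cfg, np.random.default_rng(1))
        assert lfp[0].max() - lfp[0].min() == pytest.approx(987.0, abs=1e-12)

    def test_lfp_noise_confined_below_100hz(self):
        cfg = small_config()
        rng = np.random.default_rng(2)
        noise = synth._band_limited_noise(rng, 60000, 1000.0, 25.0, 100.0)
        spec = np.abs(np.fft.rfft(noise))
        freqs = np.fft.rfftfreq(60000, 1e-3)
        assert spec[freqs > 110].max() < 1e-6 * spec.max()

    def test_mua_gain_zero_highpass_power_at_noise_floor(self, wideband_session):
        cfg, _, _ = wideband_session
        cfg0 = small_config(render_wideband=True, quiet_s=30.0, transition_s=0.0,
                            sleep_s=0.0, n_awakenings=0)
        cfg0.mua_gain = {k: 0.0 for k in cfg0.mua_gain}
        rng = np.random.default_rng(3)
        states = synth.generate_state_sequence(cfg0, rng)
        truth = synth.generate_events(states, cfg0, rng)
        wb = synth.render_wideband(truth, states, cfg0, rng)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, 300.0, btype="highpass", fs=cfg0.wideband_fs, output="sos")
        high = sosfiltfilt(sos, wb[0])
        assert high.std() == pytest.approx(cfg0.mua_noise_sd, rel=0.05)

    def test_burst_envelope_ordered_by_state_gain(self, wideband_session):
        cfg, session, truth = wideband_session
        from ticstate.mua import mua_envelope
        env = mua_envelope(session.wideband[0], cfg.wideband_fs)
        fs = cfg.wideband_fs
        n = env.size

        def mean_env_around(label):
            ons = truth.lfp_onset_s[truth.lfp_state == label]
            vals = [env[int(t * fs):int((t + 0.2) * fs)].mean()
                    for t in ons if (t + 0.2) * fs < n]
            return np.mean(vals)

        assert mean_env_around("quiet_waking") > mean_env_around("sleep")


class TestRenderUnits:
    def _lone_unit_cfg(self, **kw):
        cfg = small_config(quiet_s=100.0, transition_s=0.0, sleep_s=0.0,
                           n_awakenings=0, n_spn=1, n_fsi=0,
                           unit_rate_ln_sd=0.0, unit_mag_cv=0.0, **kw)
        cfg.lock_lost_prob = {"SPN": 0.0, "FSI": 0.0}
        cfg.lock_pattern_change_prob = 0.0
        return cfg

    def test_flat_baseline_count_within_poisson_bound(self):
        cfg = self._lone_unit_cfg()
        cfg.spn_rate = {k: 10.0 for k in cfg.spn_rate}
        cfg.spn_lock_mag = {k: 0.0 for k in cfg.spn_lock_mag}
        states = synth.generate_state_sequence(cfg, np.random.default_rng(4))
        truth = synth.generate_events(states, cfg, np.random.default_rng(4))
        units = synth.render_units(truth, states, cfg, np.random.default_rng(4))
        n = units[0].spike_times_s.size
        assert abs(n - 1000) < 3 * np.sqrt(1000)

    def test_locked_excess_matches_kernel_integral(self):
        cfg = self._lone_unit_cfg()
        cfg.spn_rate = {k: 1.0 for k in cfg.spn_rate}
        mag = 40.0
        cfg.spn_lock_mag = {k: mag for k in cfg.spn_lock_mag}
        states = synth.generate_state_sequence(cfg, np.random.default_rng(5))
        truth = synth.generate_events(states, cfg, np.random.default_rng(5))
        units = synth.render_units(truth, states, cfg, np.random.default_rng(5))
        # the locked spikes concentrate right after the events: expected
        # count per event window ~= mag * kernel integral (+ small baseline)
        k_int = mag * cfg.unit_kernel_sd_s * np.sqrt(2 * np.pi)
        in_windows = sum(
            int(((units[0].spike_times_s >= t) &
                 (units[0].spike_times_s < t + 0.15)).sum())
            for t in truth.lfp_onset_s)
        expected = truth.lfp_onset_s.size * k_int
        assert in_windows == pytest.approx(expected, abs=3 * np.sqrt(expected) + 3)

    def test_fsi_rates_ordered_wake_above_sleep(self, short_session):
        cfg, session, truth = short_session
        from ticstate.sua import firing_stats
        fsi = [u for u in session.units if u.unit_id.startswith("fsi")]
        wake = np.mean([firing_stats(u, session.states, "quiet_waking")["rate"]
                        for u in fsi])
        sleep = np.mean([firing_stats(u, session.states, "sleep")["rate"]
                         for u in fsi])
        assert wake > sleep


class TestDeterminism:
    def test_same_seed_identical_sessions(self):
        cfg = small_config()
        s1, t1 = synth.generate_session(cfg, 123, "a")
        s2, t2 = synth.generate_session(cfg, 123, "a")
        np.testing.assert_array_equal(s1.gyro, s2.gyro)
        np.testing.assert_array_equal(s1.lfp, s2.lfp)
        np.testing.assert_array_equal(t1.tic_onset_s, t2.tic_onset_s)
        for u1, u2 in zip(s1.units, s2.units):
            np.testing.assert_array_equal(u1.spike_times_s, u2.spike_times_s)

    def test_distinct_seeds_differ(self):
        cfg = small_config()
        _, t1 = synth.generate_session(cfg, 1, "a")
        _, t2 = synth.generate_session(cfg, 2, "a")
        assert t1.lfp_onset_s.size != t2.lfp_onset_s.size or \
            not np.array_equal(t1.lfp_onset_s, t2.lfp_onset_s)

    def test_study_yields_distinct_sessions(self):
        cfg = small_config(n_sessions=3)
        sessions = [t for _, t in synth.generate_study(cfg)]
        assert len(sessions) == 3
        assert not np.array_equal(sessions[0].lfp_onset_s, sessions[1].lfp_onset_s)

    def test_minimal_scenario_valid(self):
        cfg = small_config(quiet_s=5.0, transition_s=2.0, sleep_s=3.0,
                           n_awakenings=0)
        session, truth = synth.generate_session(cfg, 9, "mini")
        session.validate()
        truth.validate()


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = synth.paper_default()
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        back = synth.ScenarioConfig.from_yaml(path)
        assert back == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("not_a_parameter: 1\n")
        with pytest.raises(ValidationError, match="unknown"):
            synth.ScenarioConfig.from_yaml(path)

    def test_shipped_default_scenario_loads(self):
        from importlib import resources
        with resources.as_file(resources.files("ticstate") / "scenarios"
                               / "paper_default.yaml") as p:
            cfg = synth.ScenarioConfig.from_yaml(p)
        assert cfg == synth.paper_default()
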