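"""Unit classification, firing statistics, PLTH responses, and
state-change classes."""

import numpy as np
import pytest

from ticstate import synth
from ticstate.core import SpikeTrain, StateAnnotation
from ticstate.sua import (SuaParams, analyze_unit_state, classify_state_change,
                          classify_unit, firing_stats, response_magnitude,
                          response_significance, unit_plth, waveform_width_ms)

WAVEFORM_FS = 30000.0


def make_train(rate_hz, duration_s, width_ms, rng):
    n = rng.poisson(rate_hz * duration_s)
    return SpikeTrain("u", np.sort(rng.uniform(0, duration_s, n)),
                      mean_waveform=synth._synth_waveform(WAVEFORM_FS, width_ms),
                      waveform_fs=WAVEFORM_FS)


class TestClassifyUnit:
    def test_narrow_fast_is_fsi(self):
        rng = np.random.default_rng(0)
        train = make_train(13.0, 100.0, 0.25, rng)
        assert classify_unit(train, 100.0) == "FSI"

    def test_wide_slow_is_spn(self):
        rng = np.random.default_rng(1)
        train = make_train(2.0, 100.0, 0.70, rng)
        assert classify_unit(train, 100.0) == "SPN"

    def test_wide_fast_unclassified(self):
        rng = np.random.default_rng(2)
        train = make_train(20.0, 100.0, 0.70, rng)
        assert classify_unit(train, 100.0) == "unclassified"

    def test_missing_waveform_unclassified(self):
        train = SpikeTrain("u", np.linspace(0, 99, 500))
        assert classify_unit(train, 100.0) == "unclassified"

    def test_waveform_width_measures_trough_to_peak(self):
        w = synth._synth_waveform(WAVEFORM_FS, 0.70)
        assert waveform_width_ms(w, WAVEFORM_FS) == pytest.approx(0.70, abs=0.06)


class TestFiringStats:
    def test_regular_train(self):
        states = StateAnnotation([(0.0, 100.0, "quiet_waking")])
        train = SpikeTrain("u", np.arange(0.05, 100.0, 0.1))
        out = firing_stats(train, states, "quiet_waking")
        assert out["rate"] == pytest.approx(10.0, rel=0.01)
        assert out["isi_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(3)
        states = StateAnnotation([(0.0, 600.0, "sleep")])
        train = SpikeTrain("u", np.sort(rng.uniform(0, 600, 6000)))
        out = firing_stats(train, states, "sleep")
        assert out["isi_cv"] == pytest.approx(1.0, abs=0.1)

    def test_isis_do_not_span_interval_gaps(self):
        states = StateAnnotation([(0.0, 10.0, "sleep"), (50.0, 60.0, "sleep")])
        # regular 1 Hz within each interval; the 40-s gap must not enter
        times = np.r_[np.arange(0.5, 10.0), np.arange(50.5, 60.0)]
        train = SpikeTrain("u", times)
        out = firing_stats(train, states, "sleep")
        assert out["isi_cv"] == pytest.approx(0.0, abs=1e-9)
        assert out["rate"] == pytest.approx(1.0, rel=0.05)

    def test_too_few_spikes_flagged(self):
        states = StateAnnotation([(0.0, 10.0, "sleep")])
        out = firing_stats(SpikeTrain("u", np.array([1.0])), states, "sleep")
        assert np.isnan(out["isi_cv"]) and out["flags"]


class TestUnitPlth:
    def test_homogeneous_poisson_flat_at_rate(self):
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, 600, 6000))   # 10 Hz
        onsets = np.sort(rng.uniform(2, 598, 400))
        plth = unit_plth(spikes, onsets)
        assert plth.values.mean() == pytest.approx(10.0, rel=0.05)
        plth.validate()

    def test_no_spikes_zero_plth(self):
        plth = unit_plth(np.empty(0), np.linspace(2, 90, 20))
        np.testing.assert_array_equal(plth.values, 0.0)

    def test_low_event_count_flagged(self):
        plth = unit_plth(np.array([1.0, 2.0]), np.array([1.5]))
        assert any("low confidence" in f for f in plth.flags)

    def test_injected_locked_unit_peaks_at_kernel_latency(self, short_session):
        cfg, session, truth = short_session
        ons = truth.lfp_onset_s[truth.lfp_state == "quiet_waking"]
        # pick the FSI (highest locking magnitude, not lost in wake)
        fsi = next(u for u in session.units if u.unit_id.startswith("fsi"))
        plth = unit_plth(fsi, ons)
        peak_t = plth.times[plth.onset_index + int(np.argmax(
            plth.values[plth.onset_index:plth.onset_index + 500]))]
        assert abs(peak_t - cfg.unit_kernel_latency_s) < 0.03


class TestResponseSignificance:
    def _flat_plth_unit(self, rng, rate=5.0, n_onsets=400):
        spikes = np.sort(rng.uniform(0, 600, rng.poisson(rate * 600)))
        onsets = np.sort(rng.uniform(2, 598, n_onsets))
        return unit_plth(spikes, onsets)

    def test_flat_plth_not_significant(self):
        plth = self._flat_plth_unit(np.random.default_rng(5))
        assert response_significance(plth) == "none"

    def test_constructed_excursion_excited(self):
        rng = np.random.default_rng(6)
        from ticstate.core import Plth
        values = rng.normal(5.0, 1.0, 2000)
        values[1040:1120] = 5.0 + 3.0 * 1.0 + 2.0  # sustained > mean + 2 SD
        plth = Plth(values=values, window_s=(1.0, 1.0), n_events=50,
                    smoothing_sd_s=0.0, baseline_window_s=(-1.0, -0.5))
        assert response_significance(plth) == "excited"

    def test_constructed_suppression_inhibited(self):
        rng = np.random.default_rng(7)
        from ticstate.core import Plth
        values = rng.normal(10.0, 1.0, 2000)
        values[1040:1150] = 10.0 - 5.0
        plth = Plth(values=values, window_s=(1.0, 1.0), n_events=50,
                    smoothing_sd_s=0.0, baseline_window_s=(-1.0, -0.5))
        assert response_significance(plth) == "inhibited"

    def test_type_one_error_controlled(self):
        # unlocked Poisson units against surrogate onsets
        rng = np.random.default_rng(8)
        false_pos = sum(
            response_significance(self._flat_plth_unit(rng, n_onsets=600)) != "none"
            for _ in range(200))
        assert false_pos / 200 <= 0.08

    def test_silent_baseline_poisson_fallback(self):
        from ticstate.core import Plth
        values = np.zeros(2000)
        values[1030:1100] = 40.0
        plth = Plth(values=values, window_s=(1.0, 1.0), n_events=100,
                    smoothing_sd_s=0.0, baseline_window_s=(-1.0, -0.5))
        assert response_significance(plth) == "excited"


class TestResponseMagnitude:
    def test_flat_plth_zero(self):
        from ticstate.core import Plth
        plth = Plth(values=np.full(2000, 4.0), window_s=(1.0, 1.0), n_events=20,
                    baseline_window_s=(-1.0, -0.5))
        assert response_magnitude(plth) == pytest.approx(0.0)

    def test_arithmetic(self):
        from ticstate.core import Plth
        values = np.full(2000, 2.0)
        values[1100] = 32.0
        plth = Plth(values=values, window_s=(1.0, 1.0), n_events=20,
                    smoothing_sd_s=0.0, baseline_window_s=(-1.0, -0.5))
        assert response_magnitude(plth) == pytest.approx(30.0)

    def test_locking_gain_ordering_recovered(self):
        # parameter recovery: stronger injected locking -> larger magnitude
        from scipy.stats import spearmanr
        cfg = synth.paper_default()
        cfg.n_spn, cfg.n_fsi = 24, 0
        cfg.lock_lost_prob = {"SPN": 0.0, "FSI": 0.0}
        cfg.lock_pattern_change_prob = 0.0
        rng = np.random.default_rng(9)
        states = synth.generate_state_sequence(cfg, rng)
        truth = synth.generate_events(states, cfg, rng)
        units = synth.render_units(truth, states, cfg, rng)
        ons = truth.lfp_onset_s[truth.lfp_state == "quiet_waking"]
        mags = [response_magnitude(unit_plth(u, ons)) for u in units]
        true_mags = [d["wake_mag"] for d in truth.unit_truth]
        assert spearmanr(mags, true_mags).statistic > 0.9


class TestStateChange:
    def _response(self, values, significant):
        from ticstate.core import Plth
        plth = Plth(values=values, window_s=(1.0, 1.0), n_events=50,
                    smoothing_sd_s=0.0, baseline_window_s=(-1.0, -0.5))
        return analyze_unit_state("u", "x", plth)

    def _wake_response(self):
        values = np.full(2000, 2.0)
        values[1020:1220] = 2.0 + 30.0 * np.sin(np.linspace(0, np.pi, 200))
        return self._response(values, "excited")

    def test_flat_sleep_is_lost(self):
        wake = self._wake_response()
        sleep = self._response(np.full(2000, 2.0), "none")
        assert classify_state_change(wake, sleep) == "lost"
        assert classify_state_change(wake, None) == "lost"

    def test_halved_response_reduced_same_pattern(self):
        wake = self._wake_response()
        values = np.full(2000, 2.0)
        values[1020:1220] = 2.0 + 15.0 * np.sin(np.linspace(0, np.pi, 200))
        sleep = self._response(values, "excited")
        assert classify_state_change(wake, sleep) == "reduced_same_pattern"

    def test_halved_time_reversed_reduced_different_pattern(self):
        wake = self._wake_response()
        values = np.full(2000, 2.0)
        # same energy, shifted far later in the window: different pattern
        values[1300:1500] = 2.0 + 15.0 * np.sin(np.linspace(0, np.pi, 200))
        sleep = self._response(values, "excited")
        assert classify_state_change(wake, sleep) == "reduced_different_pattern"

    def test_increased_and_unchanged(self):
        wake = self._wake_response()
        values = np.full(2000, 2.0)
        values[1020:1220] = 2.0 + 45.0 * np.sin(np.linspace(0, np.pi, 200))
        assert classify_state_change(wake, self._response(values, "excited")) \
            == "increased"
        values = np.full(2000, 2.0)
        values[1020:1220] = 2.0 + 30.0 * np.sin(np.linspace(0, np.pi, 200))
        assert classify_state_change(wake, self._response(values, "excited")) \
            == "unchanged"
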