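"""Event detection: motor tics in the gyroscope x-axis, LFP spikes in the
low-frequency field potential, plus per-state event statistics and
shape-stability metrics.

Detection machinery (shared between the two signals): a robust amplitude
threshold -- ``|x - median| > k * 1.4826 * MAD`` -- finds super-threshold
runs, runs closer than a refractory period merge into one event, the event
peak is the extremum of the run, and the onset is found by backtracking from
the peak to the last sample within a fraction of a robust SD of baseline.
Peak-to-peak amplitude is measured on the *raw* (unfiltered) signal within
the snippet window, so filter shape never biases the intensity measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .core import EventSeries, StateAnnotation, ValidationError, state_mask

__all__ = [
    "DetectParams", "extract_lfp", "detect_lfp_spikes", "detect_tics",
    "event_waveforms", "shape_stability", "event_stats_by_state",
    "robust_stats",
]


@dataclass
class DetectParams:
    """Detection parameters (robust-SD units; calibrated on the synthetic
    noise model and exposed here)."""

    lfp_band_hz: float = 100.0           # LFP = frequencies below 100 Hz
    mua_highpass_hz: float = 300.0       # MUA = frequencies above 300 Hz
    gyro_band_hz: tuple[float, float] = (0.0, 100.0)  # detection band for gyro; lo=0 -> pure low-pass
    threshold_sd_gyro: float = 5.0
    threshold_sd_lfp: float = 4.5
    refractory_s: float = 0.45           # minimum separation between event extrema
    backtrack_sd: float = 0.5            # onset: last sample within this SD of baseline
    backtrack_frac: float = 0.01         # ... or within this fraction of the peak
    snippet_gyro_s: tuple[float, float] = (0.05, 0.38)  # (pre, post) around onset
    snippet_lfp_s: tuple[float, float] = (0.05, 0.50)

    def validate(self) -> None:
        if self.threshold_sd_gyro <= 0 or self.threshold_sd_lfp <= 0:
            raise ValidationError("thresholds must be > 0")
        if self.refractory_s < 0:
            raise ValidationError("refractory must be >= 0")


def robust_stats(x: np.ndarray) -> tuple[float, float]:
    """(median, robust SD) where robust SD = 1.4826 * MAD."""
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, 1.4826 * mad


def extract_lfp(wideband: np.ndarray, fs: float, params: DetectParams | None = None,
                out_fs: float = 1000.0) -> np.ndarray:
    """Low-pass the wideband trace below 100 Hz (zero-phase) and decimate.

    Zero-phase filtering preserves event timing; the decimation factor must
    be integral.
    """
    params = params or DetectParams()
    if fs < 2 * params.lfp_band_hz:
        raise ValidationError(f"sampling rate {fs} too low for a {params.lfp_band_hz} Hz band")
    sos = butter(4, params.lfp_band_hz, btype="lowpass", fs=fs, output="sos")
    low = sosfiltfilt(sos, np.asarray(wideband, dtype=float), axis=-1)
    step = fs / out_fs
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValidationError("output rate must integrally divide the input rate")
    return low[..., ::int(round(step))]


def _detect(detection_signal: np.ndarray, raw_signal: np.ndarray, fs: float,
            k: float, refractory_s: float, backtrack_sd: float,
            backtrack_frac: float, window_s: tuple[float, float],
            baseline_mask: np.ndarray | None = None) -> tuple[np.ndarray, ...]:
    """Shared threshold-crossing detector; returns (onset, peak, p2p) arrays.

    Events are the local maxima of the robust deviation ``|x - median|``
    exceeding ``k`` robust SDs, with a minimum peak separation equal to the
    refractory window: the lobes of one multiphasic deflection collapse onto
    its dominant extremum, while distinct events -- whose extrema are at
    least one refractory apart -- stay separate even when their threshold
    excursions nearly touch.
    """
    x = np.asarray(detection_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal contains non-finite samples")
    base = x[baseline_mask] if baseline_mask is not None else x
    med, rsd = robust_stats(base)
    dev = np.abs(x - med)
    if dev.max() == 0.0:
        return np.empty(0), np.empty(0), np.empty(0)
    # the relative floor only binds when the noise scale collapses (near-
    # noiseless signals), where zero-phase filter ringing would otherwise
    # count as micro-events
    height = max(k * rsd, 1e-3 * dev.max())
    distance = max(1, int(round(refractory_s * fs)))
    peak_idx, _ = find_peaks(dev, height=height, distance=distance)
    if peak_idx.size == 0:
        return np.empty(0), np.empty(0), np.empty(0)

    pre_n = int(round(window_s[0] * fs))
    post_n = int(round(window_s[1] * fs))
    onsets, peaks, p2ps = [], [], []
    raw = np.asarray(raw_signal, dtype=float)
    for p in peak_idx:
        # backtrack from the event extremum to the last near-baseline sample
        floor = max(backtrack_sd * rsd, backtrack_frac * dev[p], 1e-6 * dev.max())
        i = p
        lo = max(0, p - post_n)
        while i > lo and dev[i - 1] > floor:
            i -= 1
        onset = i
        w0, w1 = max(0, onset - pre_n), min(x.size, onset + post_n)
        snippet = raw[w0:w1]
        p2ps.append(float(snippet.max() - snippet.min()) if snippet.size else 0.0)
        onsets.append(onset / fs)
        peaks.append(p / fs)
    return np.asarray(onsets), np.asarray(peaks), np.asarray(p2ps)


def _label_events(onsets: np.ndarray, states: StateAnnotation | None) -> np.ndarray:
    if states is None or onsets.size == 0:
        return np.full(onsets.size, "", dtype=object)
    return np.asarray(states.label_at(onsets), dtype=object)


def detect_lfp_spikes(lfp: np.ndarray, fs: float, params: DetectParams | None = None,
                      states: StateAnnotation | None = None) -> EventSeries:
    """Detect LFP-spike events on one low-frequency field-potential trace."""
    params = params or DetectParams()
    params.validate()
    onset, peak, p2p = _detect(lfp, lfp, fs, params.threshold_sd_lfp,
                               params.refractory_s, params.backtrack_sd,
                               params.backtrack_frac, params.snippet_lfp_s)
    ev = EventSeries("lfp_spike", onset, peak, p2p, _label_events(onset, states),
                     params.snippet_lfp_s)
    ev.validate()
    return ev


def detect_tics(gyro_x: np.ndarray, fs: float, states: StateAnnotation,
                params: DetectParams | None = None) -> EventSeries:
    """Detect tic events on the gyroscope x-axis.

    Detection runs on the band-passed trace; baseline statistics come from
    quiet-waking plus sleep samples only, so voluntary-movement ('other')
    segments never contaminate the threshold.  Peak-to-peak amplitude is
    measured on the raw trace.
    """
    params = params or DetectParams()
    params.validate()
    x = np.asarray(gyro_x, dtype=float)
    lo, hi = params.gyro_band_hz
    if lo > 0:
        sos = butter(4, (lo, min(hi, 0.45 * fs)), btype="bandpass", fs=fs, output="sos")
    else:
        # a high-pass leg leaves a slow rebound tail after each large event
        # that a threshold detector mistakes for more events; drift removal
        # can be re-enabled via gyro_band_hz when the recording needs it
        sos = butter(4, min(hi, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, x)
    bmask = state_mask(states, "quiet_waking", fs, x.size) | \
        state_mask(states, "sleep", fs, x.size)
    if not bmask.any():
        raise ValidationError("no quiet_waking or sleep samples to estimate a baseline from")
    onset, peak, p2p = _detect(filt, x, fs, params.threshold_sd_gyro,
                               params.refractory_s, params.backtrack_sd,
                               params.backtrack_frac, params.snippet_gyro_s,
                               baseline_mask=bmask)
    ev = EventSeries("tic", onset, peak, p2p, _label_events(onset, states),
                     params.snippet_gyro_s)
    ev.validate()
    return ev


def event_waveforms(signal: np.ndarray, fs: float, events: EventSeries,
                    window_s: tuple[float, float] | None = None,
                    ) -> tuple[np.ndarray, int]:
    """Onset-aligned snippet matrix (events x samples).

    Events whose window falls partly outside the signal are dropped; the
    second return value counts them.
    """
    window_s = window_s or events.window_s
    pre_n = int(round(window_s[0] * fs))
    post_n = int(round(window_s[1] * fs))
    x = np.asarray(signal, dtype=float)
    rows, dropped = [], 0
    for t in events.onset_s:
        i = int(round(t * fs))
        if i - pre_n < 0 or i + post_n > x.size:
            dropped += 1
            continue
        rows.append(x[i - pre_n:i + post_n])
    mat = np.asarray(rows) if rows else np.empty((0, pre_n + post_n))
    return mat, dropped


def shape_stability(aligned: np.ndarray) -> dict:
    """Shape stability over time: chronological thirds, mean shape per third,
    Pearson correlations between the third means.

    Returns ``third_correlations`` (3x3), ``mean_shape``, and ``summary`` =
    the mean of the three pairwise correlations.  Fewer than 3 events is
    flagged undefined.
    """
    aligned = np.asarray(aligned, dtype=float)
    if aligned.shape[0] < 3:
        return {"third_correlations": np.full((3, 3), np.nan),
                "mean_shape": aligned.mean(axis=0) if aligned.size else np.empty(0),
                "summary": np.nan, "flags": ["fewer than 3 events"]}
    thirds = np.array_split(np.arange(aligned.shape[0]), 3)
    means = np.stack([aligned[ix].mean(axis=0) for ix in thirds])
    corr = np.corrcoef(means)
    pairs = [corr[0, 1], corr[0, 2], corr[1, 2]]
    return {"third_correlations": corr, "mean_shape": aligned.mean(axis=0),
            "summary": float(np.mean(pairs)), "flags": []}


def event_stats_by_state(events: EventSeries, states: StateAnnotation) -> pd.DataFrame:
    """Per-state event rate and amplitude statistics.

    Rate = events labeled L per minute of L; amplitude mean and CV over the
    peak-to-peak amplitudes in L.  A state with zero labeled time gets NaN
    rate (undefined, not zero); 'other' rows are reported but carry the
    excluded-from-comparisons flag downstream.
    """
    rows = []
    for label in ("quiet_waking", "transition", "sleep", "other"):
        dur_min = states.duration_of(label) / 60.0
        sub = events.in_state(label)
        amps = sub.p2p_amplitude
        rows.append({
            "state": label,
            "n_events": len(sub),
            "minutes": dur_min,
            "rate_per_min": len(sub) / dur_min if dur_min > 0 else np.nan,
            "amp_mean": float(amps.mean()) if amps.size else np.nan,
            "amp_cv": float(amps.std(ddof=1) / amps.mean())
            if amps.size > 1 and amps.mean() != 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("state")
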