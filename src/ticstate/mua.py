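"""Multi-unit activity (MUA) envelope and its LFP-spike-locked statistics.

The MUA band is the extracellular voltage above 300 Hz; its envelope (Hilbert
magnitude, low-passed) tracks aggregate nearby firing.  The envelope is
averaged around LFP-spike onsets into a peri-LFP-spike time histogram (PLTH,
1-ms bins, Gaussian-smoothed SD 10 ms) from which an SNR and duration/latency
metrics are read out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from . import coupling
from .core import Plth, ValidationError

__all__ = ["MuaParams", "mua_envelope", "envelope_plth", "envelope_snr",
           "mua_duration_latency", "smooth_plth_values"]


@dataclass
class MuaParams:
    highpass_hz: float = 300.0
    envelope_lowpass_hz: float = 50.0
    bin_width_s: float = 0.001
    smoothing_sd_s: float = 0.010
    window_s: tuple[float, float] = (0.5, 1.0)          # (pre, post)
    baseline_window_s: tuple[float, float] = (-0.2, -0.15)  # 150-200 ms pre-onset
    duration_criterion_sd: float = 2.0

    def validate(self, fs: float | None = None) -> None:
        if self.highpass_hz <= 0 or self.envelope_lowpass_hz <= 0:
            raise ValidationError("cutoffs must be positive")
        if fs is not None and fs <= 2 * self.highpass_hz:
            raise ValidationError(f"sampling rate {fs} too low for a "
                                  f"{self.highpass_hz} Hz high-pass")


def mua_envelope(wideband: np.ndarray, fs: float,
                 params: MuaParams | None = None) -> np.ndarray:
    """High-pass above 300 Hz (zero-phase), analytic-signal magnitude, then
    zero-phase low-pass; clipped at zero (the low-pass can undershoot)."""
    params = params or MuaParams()
    params.validate(fs)
    x = np.asarray(wideband, dtype=float)
    sos_hp = butter(4, params.highpass_hz, btype="highpass", fs=fs, output="sos")
    high = sosfiltfilt(sos_hp, x, axis=-1)
    env = np.abs(hilbert(high, axis=-1))
    sos_lp = butter(4, params.envelope_lowpass_hz, btype="lowpass", fs=fs, output="sos")
    return np.clip(sosfiltfilt(sos_lp, env, axis=-1), 0.0, None)


def smooth_plth_values(values: np.ndarray, bin_width_s: float,
                       smoothing_sd_s: float) -> np.ndarray:
    """Gaussian smoothing (SD in seconds, truncated at 4 SD) that preserves
    the integral of an interior impulse."""
    if smoothing_sd_s <= 0:
        return np.asarray(values, dtype=float)
    sd_bins = smoothing_sd_s / bin_width_s
    return gaussian_filter1d(np.asarray(values, dtype=float), sd_bins,
                             mode="nearest", truncate=4.0)


def envelope_plth(envelope: np.ndarray, fs: float, onsets: np.ndarray,
                  params: MuaParams | None = None) -> Plth:
    """Event-aligned mean of the envelope in 1-ms bins, Gaussian-smoothed.

    Events whose window exceeds the signal are dropped; an empty onset list
    yields a flagged empty-ish PLTH (n_events 0).
    """
    params = params or MuaParams()
    x = np.asarray(envelope, dtype=float)
    pre, post = params.window_s
    bin_n = int(round(params.bin_width_s * fs))
    if bin_n < 1:
        raise ValidationError("bin width below one sample")
    pre_n = int(round(pre * fs))
    post_n = int(round(post * fs))
    n_bins = (pre_n + post_n) // bin_n
    rows = []
    for t in np.asarray(onsets, dtype=float):
        i = int(round(t * fs))
        if i - pre_n < 0 or i + post_n > x.size:
            continue
        seg = x[i - pre_n:i - pre_n + n_bins * bin_n]
        rows.append(seg.reshape(n_bins, bin_n).mean(axis=1))
    if not rows:
        return Plth(values=np.zeros(n_bins), window_s=(pre, post), n_events=0,
                    bin_width_s=params.bin_width_s,
                    smoothing_sd_s=params.smoothing_sd_s,
                    baseline_window_s=params.baseline_window_s,
                    flags=["no usable events"])
    mean = np.mean(rows, axis=0)
    values = smooth_plth_values(mean, params.bin_width_s, params.smoothing_sd_s)
    return Plth(values=values, window_s=(pre, post), n_events=len(rows),
                bin_width_s=params.bin_width_s, smoothing_sd_s=params.smoothing_sd_s,
                baseline_window_s=params.baseline_window_s)


def envelope_snr(plth: Plth) -> dict:
    """Peri-event SNR of the envelope PLTH.

    Baseline = the 150-200 ms pre-onset bins.  Two readouts: ``snr_ratio`` =
    (max - baseline mean) / baseline SD (the headline metric) and
    ``snr_delta`` = max - baseline mean, in envelope units (uV), since the
    baseline-subtracted amplitude is also a natural report of burst size.
    """
    base = plth.values[plth.baseline_slice()]
    if base.size < 2:
        return {"snr_ratio": np.nan, "snr_delta": np.nan,
                "flags": ["baseline window too small"]}
    bmean = float(base.mean())
    bsd = float(base.std(ddof=1))
    peak = float(plth.values[plth.onset_index:].max())
    delta = peak - bmean
    if bsd == 0.0:
        if delta == 0.0:  # perfectly flat PLTH: no response at all
            return {"snr_ratio": 0.0, "snr_delta": 0.0, "flags": []}
        return {"snr_ratio": np.nan, "snr_delta": delta,
                "flags": ["zero baseline SD"]}
    return {"snr_ratio": delta / bsd, "snr_delta": delta, "flags": []}


def mua_duration_latency(plth: Plth, params: MuaParams | None = None) -> dict:
    """Duration and latency of the envelope PLTH deflection, using the same
    operators as the LFP/gyro mean-trace metrics."""
    params = params or MuaParams()
    fs = 1.0 / plth.bin_width_s
    cp = coupling.CouplingParams(
        duration_criterion_sd=params.duration_criterion_sd,
        baseline_window_s=(-0.25, -0.05),
    )
    dur = coupling.event_duration(plth.values, fs, plth.onset_index, cp)
    lat = coupling.event_latency(plth.values, fs, plth.onset_index, cp)
    return {"duration_s": dur["duration_s"], "latency_s": lat["latency_s"],
            "flags": dur["flags"] + lat["flags"]}
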