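"""Single-unit analysis: SPN/FSI classification, per-state firing statistics,
peri-LFP-spike histograms (PLTH), response significance and magnitude, and
wake-to-sleep response-change classes.

Striatal units are classified by waveform width and firing rate: fast-spiking
interneurons (FSI) are narrow and fast, spiny projection neurons (SPN) wide
and slow.  A unit's LFP-spike-locked response is significant when its
smoothed PLTH stays two baseline SDs away from the baseline mean for a
sustained run of bins; response magnitude is the maximal post-onset PLTH
rate minus the mean rate 500-1000 ms before onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Plth, SpikeTrain, StateAnnotation, ValidationError
from .mua import smooth_plth_values

__all__ = [
    "SuaParams", "UnitResponse", "classify_unit", "firing_stats", "unit_plth",
    "response_significance", "response_magnitude", "classify_state_change",
]


@dataclass
class SuaParams:
    """Unit-analysis parameters.

    ``n_consec_s`` (the sustained-run requirement for significance) is
    calibrated by Monte-Carlo on the smoothed-PLTH noise model so that an
    unlocked Poisson unit is called significant in at most ~5% of cases; the
    10-ms smoothing makes noise excursions above 2 SD last ~15 ms on
    average, so the run requirement must clearly exceed that scale.
    """

    bin_width_s: float = 0.001
    smoothing_sd_s: float = 0.010
    window_s: tuple[float, float] = (1.0, 1.0)            # (pre, post)
    baseline_window_s: tuple[float, float] = (-1.0, -0.5)  # 500-1000 ms pre-onset
    response_window_s: tuple[float, float] = (0.0, 0.5)
    criterion_sd: float = 2.0
    n_consec_s: float = 0.05
    min_events: int = 10
    # waveform/rate classification thresholds (common striatal practice)
    fsi_max_width_ms: float = 0.4
    fsi_min_rate_hz: float = 5.0
    spn_min_width_ms: float = 0.55
    spn_max_rate_hz: float = 5.0
    min_spikes_classify: int = 100
    # state-change thresholds
    reduced_ratio: float = 0.8
    increased_ratio: float = 1.2
    pattern_corr_threshold: float = 0.5


@dataclass
class UnitResponse:
    """One unit's PLTH-based response in one state."""

    unit_id: str
    state: str
    plth: Plth
    significant: str              # {excited, inhibited, none}
    magnitude: float              # spikes/s above baseline
    pattern: np.ndarray = field(default_factory=lambda: np.empty(0))
    flags: list[str] = field(default_factory=list)


def waveform_width_ms(waveform: np.ndarray, fs: float) -> float:
    """Trough-to-peak width (ms): time from the global trough to the
    subsequent maximum."""
    w = np.asarray(waveform, dtype=float)
    trough = int(np.argmin(w))
    after = w[trough:]
    peak = trough + int(np.argmax(after))
    return (peak - trough) / fs * 1000.0


def classify_unit(train: SpikeTrain, duration_s: float,
                  params: SuaParams | None = None) -> str:
    """Putative cell type from waveform width and session-mean rate.

    FSI: narrow (< 0.4 ms trough-to-peak) and fast (> 5 spikes/s);
    SPN: wide (>= 0.55 ms) and slow (< 5 spikes/s); everything else --
    including units with no waveform or too few spikes -- is unclassified.
    """
    params = params or SuaParams()
    if train.mean_waveform is None or not train.waveform_fs:
        return "unclassified"
    if train.spike_times_s.size < params.min_spikes_classify or duration_s <= 0:
        return "unclassified"
    width = waveform_width_ms(train.mean_waveform, train.waveform_fs)
    rate = train.spike_times_s.size / duration_s
    if width < params.fsi_max_width_ms and rate > params.fsi_min_rate_hz:
        return "FSI"
    if width >= params.spn_min_width_ms and rate < params.spn_max_rate_hz:
        return "SPN"
    return "unclassified"


def firing_stats(train: SpikeTrain, states: StateAnnotation, label: str) -> dict:
    """Firing rate and ISI coefficient of variation within one state.

    The rate is spike count over total labeled time; ISIs are computed only
    within intervals (ISIs spanning gaps between same-label intervals are
    discarded).  Fewer than 2 spikes leaves the CV undefined (flagged).
    """
    total = states.duration_of(label)
    if total <= 0:
        return {"rate": np.nan, "isi_cv": np.nan, "n_spikes": 0,
                "flags": ["zero state duration"]}
    t = train.spike_times_s
    n = 0
    isis = []
    for start, end in states.intervals_of(label):
        seg = t[(t >= start) & (t < end)]
        n += seg.size
        if seg.size >= 2:
            isis.append(np.diff(seg))
    isis = np.concatenate(isis) if isis else np.empty(0)
    out = {"rate": n / total, "n_spikes": int(n), "flags": []}
    if isis.size >= 2 and isis.mean() > 0:
        out["isi_cv"] = float(isis.std(ddof=1) / isis.mean())
    else:
        out["isi_cv"] = np.nan
        out["flags"].append("too few spikes for ISI CV")
    return out


def unit_plth(train: SpikeTrain | np.ndarray, onsets: np.ndarray,
              params: SuaParams | None = None) -> Plth:
    """Peri-event spike-rate histogram: counts per 1-ms bin divided by
    (n_events * bin width), Gaussian-smoothed (SD 10 ms).

    Fewer than ``min_events`` onsets flags the PLTH low-confidence.
    """
    params = params or SuaParams()
    spikes = train.spike_times_s if isinstance(train, SpikeTrain) else \
        np.asarray(train, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    pre, post = params.window_s
    n_bins = int(round((pre + post) / params.bin_width_s))
    counts = np.zeros(n_bins)
    n_used = 0
    for t in onsets:
        rel = spikes[(spikes >= t - pre) & (spikes < t + post)] - t
        idx = np.floor((rel + pre) / params.bin_width_s).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1.0)
        n_used += 1
    flags = []
    if n_used < params.min_events:
        flags.append("low confidence: fewer than "
                     f"{params.min_events} events")
    if n_used == 0:
        rate = counts
    else:
        rate = counts / (n_used * params.bin_width_s)
    values = smooth_plth_values(rate, params.bin_width_s, params.smoothing_sd_s)
    return Plth(values=values, window_s=(pre, post), n_events=max(n_used, 0),
                bin_width_s=params.bin_width_s, smoothing_sd_s=params.smoothing_sd_s,
                baseline_window_s=params.baseline_window_s, flags=flags)


def _baseline_of(plth: Plth, params: SuaParams) -> tuple[float, float]:
    b0, b1 = params.baseline_window_s
    pre = plth.window_s[0]
    sl = slice(int(round((b0 + pre) / plth.bin_width_s)),
               int(round((b1 + pre) / plth.bin_width_s)))
    base = plth.values[sl]
    if base.size < 2:
        raise ValidationError("baseline window outside the PLTH")
    return float(base.mean()), float(base.std(ddof=1))


def response_significance(plth: Plth, params: SuaParams | None = None) -> str:
    """{excited, inhibited, none}: the smoothed PLTH must stay 2 baseline SDs
    above (below) the baseline mean for at least ``n_consec_s`` of
    consecutive bins inside the post-onset response window.

    A zero baseline SD (e.g. a silent baseline) falls back to the Poisson
    counting SD of the smoothed rate estimate.
    """
    params = params or SuaParams()
    bmean, bsd = _baseline_of(plth, params)
    if bsd == 0.0:
        # Poisson fallback: var of the smoothed rate estimate at rate bmean
        eff = 1.0 / (2.0 * np.sqrt(np.pi) * (params.smoothing_sd_s / plth.bin_width_s))
        n = max(plth.n_events, 1)
        bsd = float(np.sqrt(max(bmean, 1e-12) / (n * plth.bin_width_s) * eff))
        if bsd == 0.0:
            bsd = 1e-12
    r0, r1 = params.response_window_s
    pre = plth.window_s[0]
    sl = slice(int(round((r0 + pre) / plth.bin_width_s)),
               int(round((r1 + pre) / plth.bin_width_s)))
    seg = plth.values[sl]
    need = max(1, int(round(params.n_consec_s / plth.bin_width_s)))

    def longest_run(mask: np.ndarray) -> int:
        best = cur = 0
        for m in mask:
            cur = cur + 1 if m else 0
            best = max(best, cur)
        return best

    hi = longest_run(seg > bmean + params.criterion_sd * bsd)
    lo = longest_run(seg < bmean - params.criterion_sd * bsd)
    # when both directions sustain a run, the larger deviation wins
    if hi >= need and lo >= need:
        up = float(seg.max() - bmean)
        down = float(bmean - seg.min())
        return "excited" if up >= down else "inhibited"
    if hi >= need:
        return "excited"
    if lo >= need:
        return "inhibited"
    return "none"


def response_magnitude(plth: Plth, params: SuaParams | None = None) -> float:
    """Max post-onset PLTH rate minus the 500-1000 ms pre-onset baseline mean
    (spikes/s)."""
    params = params or SuaParams()
    bmean, _ = _baseline_of(plth, params)
    r0, r1 = params.response_window_s
    pre = plth.window_s[0]
    sl = slice(int(round((r0 + pre) / plth.bin_width_s)),
               int(round((r1 + pre) / plth.bin_width_s)))
    return float(plth.values[sl].max() - bmean)


def _pattern_vector(plth: Plth, params: SuaParams) -> np.ndarray:
    """Unit-norm baseline-subtracted response-window PLTH."""
    bmean, _ = _baseline_of(plth, params)
    r0, r1 = params.response_window_s
    pre = plth.window_s[0]
    sl = slice(int(round((r0 + pre) / plth.bin_width_s)),
               int(round((r1 + pre) / plth.bin_width_s)))
    v = plth.values[sl] - bmean
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def analyze_unit_state(unit_id: str, state: str, plth: Plth,
                       params: SuaParams | None = None) -> UnitResponse:
    params = params or SuaParams()
    sig = response_significance(plth, params)
    mag = response_magnitude(plth, params)
    return UnitResponse(unit_id=unit_id, state=state, plth=plth,
                        significant=sig, magnitude=mag,
                        pattern=_pattern_vector(plth, params), flags=plth.flags)


def classify_state_change(wake: UnitResponse, sleep: UnitResponse | None,
                          params: SuaParams | None = None) -> str:
    """Wake-to-sleep response-change class for a unit with a significant wake
    response.

    * ``lost``: no significant sleep response (or no sleep PLTH at all);
    * magnitude ratio sleep/wake < 0.8 -> ``reduced_same_pattern`` or
      ``reduced_different_pattern`` by the Pearson correlation of the
      normalized PLTH patterns against a threshold;
    * ratio > 1.2 -> ``increased``; otherwise ``unchanged``.
    """
    params = params or SuaParams()
    if wake.significant == "none":
        raise ValidationError("state-change class defined only for units with a "
                              "significant wake response")
    if sleep is None or sleep.significant == "none":
        return "lost"
    ratio = sleep.magnitude / wake.magnitude if wake.magnitude != 0 else np.inf
    if ratio < params.reduced_ratio:
        if wake.pattern.size == sleep.pattern.size and wake.pattern.size > 1:
            c = float(np.corrcoef(wake.pattern, sleep.pattern)[0, 1])
        else:
            c = np.nan
        same = np.isfinite(c) and c >= params.pattern_corr_threshold
        return "reduced_same_pattern" if same else "reduced_different_pattern"
    if ratio > params.increased_ratio:
        return "increased"
    return "unchanged"
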