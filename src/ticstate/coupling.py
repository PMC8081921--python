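"""Tic <-> LFP-spike relationship metrics, per behavioral state.

Covers the dissociation analyses: peri-event averages of one signal aligned
to the other's event onsets, tic/LFP-spike co-occurrence, event duration and
latency-to-maximal-change measured on session-mean aligned traces, and
magnitude correlations within and across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import EventSeries, StateAnnotation, ValidationError

__all__ = [
    "CouplingParams", "peri_event_average", "co_occurrence_fraction",
    "event_duration", "event_latency", "magnitude_correlation",
    "paired_amplitudes",
]


@dataclass
class CouplingParams:
    """Windows and criteria for the coupling analyses.

    ``co_window_s``: a tic onset inside [LFP onset + lo, LFP onset + hi]
    counts as co-occurring.  ``duration_criterion_sd``: the mean aligned
    trace counts as "in event" while more than this many baseline SDs from
    the baseline mean; sub-threshold gaps up to ``max_gap_s`` are bridged so
    a biphasic deflection's zero crossing does not split the run.
    """

    co_window_s: tuple[float, float] = (0.0, 0.5)
    peri_window_s: tuple[float, float] = (0.5, 1.0)   # (pre, post)
    duration_criterion_sd: float = 2.0
    duration_floor_frac: float = 0.05    # threshold never below this fraction of the peak
    min_run_s: float = 0.02              # runs shorter than this are noise, not lobes
    max_gap_s: float = 0.05
    baseline_window_s: tuple[float, float] = (-0.25, -0.05)  # relative to onset

    def validate(self) -> None:
        if self.co_window_s[1] <= self.co_window_s[0]:
            raise ValidationError("empty co-occurrence window")
        if self.duration_criterion_sd <= 0:
            raise ValidationError("duration criterion must be > 0")
        if min(self.peri_window_s) <= 0:
            raise ValidationError("peri-event window must be positive")


def peri_event_average(signal: np.ndarray, fs: float, onsets: np.ndarray,
                       window_s: tuple[float, float] = (0.5, 1.0)) -> dict:
    """Pointwise mean and SEM of onset-aligned snippets.

    Events whose window exceeds the signal are dropped.  Returns ``mean``,
    ``sem``, ``times`` (s, relative to onset), ``n_events`` and ``flags``.
    """
    x = np.asarray(signal, dtype=float)
    pre_n = int(round(window_s[0] * fs))
    post_n = int(round(window_s[1] * fs))
    rows = []
    for t in np.asarray(onsets, dtype=float):
        i = int(round(t * fs))
        if i - pre_n < 0 or i + post_n > x.size:
            continue
        rows.append(x[i - pre_n:i + post_n])
    if not rows:
        return {"mean": np.empty(0), "sem": np.empty(0), "times": np.empty(0),
                "n_events": 0, "flags": ["no usable events"]}
    mat = np.asarray(rows)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.zeros_like(mean)
    times = (np.arange(mean.size) - pre_n) / fs
    return {"mean": mean, "sem": sem, "times": times, "n_events": mat.shape[0],
            "flags": []}


def co_occurrence_fraction(lfp_events: EventSeries | np.ndarray,
                           tic_events: EventSeries | np.ndarray,
                           window_s: tuple[float, float] = (0.0, 0.5),
                           states: StateAnnotation | None = None,
                           label: str | None = None) -> dict:
    """Fraction of LFP spikes (in one state) with a co-occurring tic.

    A tic co-occurs when its onset falls within ``[lfp_onset + lo,
    lfp_onset + hi]``; matching is greedy one-to-one in time order, so each
    tic can serve at most one LFP spike.  Zero LFP spikes in the state is
    undefined (flagged), not zero.
    """
    lfp_on = lfp_events.onset_s if isinstance(lfp_events, EventSeries) else \
        np.asarray(lfp_events, dtype=float)
    tic_on = tic_events.onset_s if isinstance(tic_events, EventSeries) else \
        np.asarray(tic_events, dtype=float)
    if label is not None:
        if isinstance(lfp_events, EventSeries):
            lfp_on = lfp_events.in_state(label).onset_s
        elif states is not None:
            lfp_on = lfp_on[[states.label_at(t) == label for t in lfp_on]]
    lfp_on = np.sort(lfp_on)
    tic_on = np.sort(tic_on)
    if lfp_on.size == 0:
        return {"fraction": np.nan, "n_lfp": 0, "n_matched": 0,
                "flags": ["no LFP spikes in state"]}
    lo, hi = window_s
    matched = 0
    j = 0
    for t in lfp_on:
        while j < tic_on.size and tic_on[j] < t + lo:
            j += 1
        if j < tic_on.size and tic_on[j] <= t + hi:
            matched += 1
            j += 1          # each tic matches at most one LFP spike
    return {"fraction": matched / lfp_on.size, "n_lfp": int(lfp_on.size),
            "n_matched": matched, "flags": []}


def _baseline_stats(trace: np.ndarray, fs: float, onset_idx: int,
                    baseline_window_s: tuple[float, float]) -> tuple[float, float]:
    b0 = onset_idx + int(round(baseline_window_s[0] * fs))
    b1 = onset_idx + int(round(baseline_window_s[1] * fs))
    b0, b1 = max(b0, 0), max(b1, 1)
    if b1 <= b0:
        raise ValidationError("baseline window empty or after onset")
    base = trace[b0:b1]
    return float(base.mean()), float(base.std(ddof=1)) if base.size > 1 else 0.0


def event_duration(trace: np.ndarray, fs: float, onset_idx: int,
                   params: CouplingParams | None = None) -> dict:
    """Duration of the mean event deflection (s).

    The trace counts as super-threshold while ``|trace - baseline mean| >
    criterion * baseline SD``; gaps up to ``max_gap_s`` are bridged, and the
    duration is the length of the run containing the global extremum.  No
    super-threshold run yields 0 with a flag.  The threshold never drops
    below ``duration_floor_frac`` of the peak deviation, so a near-noiseless
    baseline cannot make the whole trace count as event.
    """
    params = params or CouplingParams()
    trace = np.asarray(trace, dtype=float)
    bmean, bsd = _baseline_stats(trace, fs, onset_idx, params.baseline_window_s)
    dev = np.abs(trace - bmean)
    threshold = max(params.duration_criterion_sd * bsd,
                    params.duration_floor_frac * dev.max(), 1e-12)
    above = dev > threshold
    if not above.any():
        return {"duration_s": 0.0, "flags": ["no super-threshold run"]}
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    raw_starts = np.r_[idx[0], idx[breaks + 1]]
    raw_ends = np.r_[idx[breaks], idx[-1]]
    peak = int(np.argmax(dev))
    peak_run = int(np.flatnonzero((raw_starts <= peak) & (peak <= raw_ends))[0])

    # isolated brief crossings are noise, not deflection lobes: drop them
    # before bridging, otherwise white-noise flickers chain runs together
    min_run = max(1, int(round(params.min_run_s * fs)))
    long_mask = (raw_ends - raw_starts + 1) >= min_run
    if not long_mask[peak_run]:
        duration = (raw_ends[peak_run] - raw_starts[peak_run] + 1) / fs
        return {"duration_s": float(duration), "flags": ["brief deflection"]}
    starts, ends = raw_starts[long_mask], raw_ends[long_mask]
    # bridge sub-threshold gaps (the zero crossing of a biphasic deflection)
    gap = max(1, int(round(params.max_gap_s * fs)))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] - 1 <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    for s, e in merged:
        if s <= peak <= e:
            return {"duration_s": float((e - s + 1) / fs), "flags": []}
    # unreachable: the peak run always survives into a merged run
    return {"duration_s": 0.0, "flags": ["extremum outside merged runs"]}


def event_latency(trace: np.ndarray, fs: float, onset_idx: int,
                  params: CouplingParams | None = None) -> dict:
    """Latency (s) from onset to the global absolute extremum of the
    baseline-subtracted mean trace ("latency to the maximal change")."""
    params = params or CouplingParams()
    trace = np.asarray(trace, dtype=float)
    bmean, _ = _baseline_stats(trace, fs, onset_idx, params.baseline_window_s)
    dev = np.abs(trace - bmean)
    if np.allclose(dev, 0.0):
        return {"latency_s": np.nan, "flags": ["flat trace"]}
    peak = int(np.argmax(dev[onset_idx:])) + onset_idx
    return {"latency_s": (peak - onset_idx) / fs, "flags": []}


def paired_amplitudes(lfp_events: EventSeries, tic_events: EventSeries,
                      window_s: tuple[float, float] = (0.0, 0.5),
                      label: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(LFP p2p, tic p2p) pairs via the same greedy one-to-one matching."""
    lfp = lfp_events.in_state(label) if label else lfp_events
    order = np.argsort(lfp.onset_s)
    tic_order = np.argsort(tic_events.onset_s)
    tic_on = tic_events.onset_s[tic_order]
    tic_amp = tic_events.p2p_amplitude[tic_order]
    lo, hi = window_s
    a_lfp, a_tic = [], []
    j = 0
    for t, amp in zip(lfp.onset_s[order], lfp.p2p_amplitude[order]):
        while j < tic_on.size and tic_on[j] < t + lo:
            j += 1
        if j < tic_on.size and tic_on[j] <= t + hi:
            a_lfp.append(amp)
            a_tic.append(tic_amp[j])
            j += 1
    return np.asarray(a_lfp), np.asarray(a_tic)


def magnitude_correlation(lfp_amp: np.ndarray, tic_amp: np.ndarray) -> dict:
    """Per-event Pearson correlation between LFP-spike magnitude and tic
    intensity (within one session/state); >= 3 pairs required."""
    lfp_amp = np.asarray(lfp_amp, dtype=float)
    tic_amp = np.asarray(tic_amp, dtype=float)
    if lfp_amp.size < 3:
        return {"r": np.nan, "p": np.nan, "n": int(lfp_amp.size),
                "flags": ["fewer than 3 pairs"]}
    if lfp_amp.std() == 0 or tic_amp.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": int(lfp_amp.size),
                "flags": ["degenerate variance"]}
    r, p = sps.pearsonr(lfp_amp, tic_amp)
    return {"r": float(r), "p": float(p), "n": int(lfp_amp.size), "flags": []}


def across_session_r2(session_lfp_means: np.ndarray,
                      session_tic_means: np.ndarray) -> dict:
    """Across-session magnitude relation: OLS of session-mean tic amplitude
    on session-mean LFP magnitude; reports r^2 (and the regression p)."""
    x = np.asarray(session_lfp_means, dtype=float)
    y = np.asarray(session_tic_means, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return {"r2": np.nan, "p": np.nan, "n": int(x.size),
                "flags": ["fewer than 3 sessions"]}
    if x.std() == 0 or y.std() == 0:
        return {"r2": np.nan, "p": np.nan, "n": int(x.size),
                "flags": ["degenerate variance"]}
    r, p = sps.pearsonr(x, y)
    return {"r2": float(r * r), "p": float(p), "n": int(x.size), "flags": []}
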