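"""Synthetic session generator.

Emulates a single sleep-wake-cycle recording from the chronic striatal
disinhibition model: stereotyped motor tics in the head gyroscope whose rate
and amplitude collapse during sleep, striatal "LFP spikes" (large stereotyped
field-potential deflections) whose rate and magnitude are state-invariant,
probabilistic tic/LFP-spike pairing that disappears in sleep, multi-unit
bursts and single-unit firing entrained to the LFP spikes with entrainment
collapsing in sleep.

The generative model, per session:

* one quiet-waking block, one transition block (split into drowsy
  micro-intervals), one sleep block optionally fragmented by brief 'other'
  awakenings;
* LFP spikes: a refractory Poisson (renewal) process with state-dependent
  rate; peak-to-peak amplitude lognormal around a per-session mean;
* tics: each LFP spike spawns a tic with state-dependent probability, the tic
  onset lagging the LFP onset by a fixed delay, plus a small residual
  unpaired-tic Poisson process so the total tic rate hits its own target;
  tic amplitude lognormal, its mean decaying exponentially through the
  transition block toward the sleep mean;
* session-level jitter: rates and amplitude means are drawn per session
  around the configured group means with realistic across-session spread; a
  shared amplitude gain couples tic and LFP-spike magnitudes across sessions;
* rendering: gyroscope x-axis = Gaussian noise + per-tic kernel (one-cycle
  damped-sinusoid shape, 350 ms) scaled to the event's peak-to-peak
  amplitude; LFP = per-event biphasic kernel (sharp negative / slow positive,
  540 ms) + band-limited pink noise; optional wideband adds >300 Hz noise
  amplitude-modulated by an LFP-spike-locked burst envelope;
* units: inhomogeneous Poisson spike trains, baseline rate by cell type
  (SPN/FSI) and state plus an LFP-spike-locked rate kernel whose gain
  collapses (or changes pattern) in sleep.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .core import (STATE_LABELS, SessionRecording, SpikeTrain, StateAnnotation,
                   ValidationError)

__all__ = [
    "ScenarioConfig", "GroundTruth", "paper_default",
    "generate_state_sequence", "generate_events",
    "render_gyro", "render_lfp", "render_wideband", "render_units",
    "generate_session", "generate_study",
    "tic_kernel", "lfp_kernel", "burst_kernel",
]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal with the given arithmetic mean and coefficient of variation."""
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    s2 = np.log1p(cv * cv)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size)


def _unit_gain(rng: np.random.Generator, ln_sd: float, size=None):
    """Mean-1 lognormal gain with the given log-SD."""
    return rng.lognormal(-ln_sd * ln_sd / 2.0, ln_sd, size)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """All generator parameters; the defaults are the study conditions.

    Rates are group means per minute; the per-state dictionaries are keyed by
    behavioral-state label.  'other' models brief awakenings, during which
    tic expression resembles quiet waking; events there are excluded from all
    state comparisons downstream.
    """

    seed: int = 0
    n_sessions: int = 18

    # state-block structure (s)
    quiet_s: float = 600.0
    transition_s: float = 240.0
    sleep_s: float = 600.0
    n_awakenings: int = 2          # brief awakenings fragmenting sleep
    awakening_s: float = 10.0
    transition_micro_s: float = 30.0   # drowsy micro-interval granularity

    # sampling
    gyro_fs: float = 1000.0
    lfp_fs: float = 1000.0
    wideband_fs: float = 10000.0
    render_wideband: bool = False
    n_electrodes: int = 1

    # LFP spikes
    lfp_rate_per_min: dict = field(default_factory=lambda: {
        "quiet_waking": 68.0, "transition": 68.0, "sleep": 60.0, "other": 68.0})
    lfp_p2p_mean: dict = field(default_factory=lambda: {
        "quiet_waking": 1054.0, "transition": 1054.0, "sleep": 932.0, "other": 1054.0})
    lfp_p2p_cv: dict = field(default_factory=lambda: {
        "quiet_waking": 0.24, "transition": 0.24, "sleep": 0.26, "other": 0.24})
    lfp_kernel_s: float = 0.54
    lfp_kernel_latency_s: float = 0.075   # onset -> negative trough
    refractory_s: float = 0.5

    # tics
    tic_rate_per_min: dict = field(default_factory=lambda: {
        "quiet_waking": 65.0, "transition": 62.0, "sleep": 3.0, "other": 65.0})
    pairing_prob: dict = field(default_factory=lambda: {
        "quiet_waking": 0.9, "transition": 0.85, "sleep": 0.0, "other": 0.9})
    tic_amp_mean: dict = field(default_factory=lambda: {
        "quiet_waking": 119.0, "sleep": 5.0, "other": 80.0})
    tic_amp_cv: dict = field(default_factory=lambda: {
        "quiet_waking": 0.45, "transition": 0.45, "sleep": 0.49, "other": 0.45})
    sleep_tic_session_prob: float = 7.0 / 18.0   # sessions expressing sleep tics
    sleep_tic_rate_cv: float = 0.7
    tic_lag_s: float = 0.072           # tic onset lag after paired LFP onset
    gyro_kernel_s: float = 0.35
    gyro_kernel_latency_s: float = 0.075  # onset -> positive peak within the tic

    # across-session jitter
    rate_session_cv: dict = field(default_factory=lambda: {
        "quiet_waking": 0.29, "sleep": 0.35})
    amp_gain_shared_ln_sd: float = 0.48
    amp_gain_tic_ln_sd: float = 0.26
    amp_gain_lfp_ln_sd: float = 0.15

    # noise
    gyro_noise_sd: float = 0.15        # deg/s per raw sample
    lfp_noise_sd: float = 25.0         # uV, band-limited < 100 Hz
    mua_noise_sd: float = 5.0          # uV, band-limited > 300 Hz

    # MUA burst envelope locked to LFP onsets
    mua_gain: dict = field(default_factory=lambda: {
        "quiet_waking": 4.6, "transition": 3.0, "sleep": 1.25, "other": 4.6})
    # burst-kernel mode; the measured PLTH latency lands near 46 ms after the
    # envelope low-pass and histogram smoothing shift the asymmetric bump
    mua_kernel_latency_s: float = 0.028
    mua_kernel_ln_sd: float = 0.65

    # single units
    n_spn: int = 2
    n_fsi: int = 3
    spn_rate: dict = field(default_factory=lambda: {
        "quiet_waking": 2.25, "transition": 2.25, "sleep": 2.30, "other": 2.25})
    fsi_rate: dict = field(default_factory=lambda: {
        "quiet_waking": 13.12, "transition": 13.12, "sleep": 7.72, "other": 13.12})
    unit_rate_ln_sd: float = 0.6       # across-unit baseline-rate spread
    spn_lock_mag: dict = field(default_factory=lambda: {
        "quiet_waking": 30.0, "transition": 30.0, "sleep": 6.4, "other": 30.0})
    fsi_lock_mag: dict = field(default_factory=lambda: {
        "quiet_waking": 52.6, "transition": 52.6, "sleep": 19.9, "other": 52.6})
    unit_mag_cv: float = 0.6           # across-unit locking-gain spread
    unit_kernel_sd_s: float = 0.020    # width of the event-locked burst (rate kernel)
    unit_kernel_latency_s: float = 0.046
    lock_lost_prob: dict = field(default_factory=lambda: {"SPN": 0.39, "FSI": 0.48})
    lock_pattern_change_prob: float = 0.3
    waveform_fs: float = 30000.0

    def validate(self) -> None:
        for d in (self.lfp_rate_per_min, self.tic_rate_per_min, self.pairing_prob):
            for lbl, v in d.items():
                if lbl not in STATE_LABELS:
                    raise ValidationError(f"unknown state label {lbl!r} in config")
                if v < 0:
                    raise ValidationError("rates/probabilities must be >= 0")
        for lbl, p in self.pairing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("pairing_prob must lie in [0, 1]")
        if min(self.quiet_s, self.transition_s, self.sleep_s) < 0:
            raise ValidationError("state durations must be >= 0")
        if self.quiet_s + self.transition_s + self.sleep_s <= 0:
            raise ValidationError("zero-length scenario")
        if self.refractory_s < 0:
            raise ValidationError("refractory must be >= 0")
        max_rate = max(self.lfp_rate_per_min.values()) / 60.0
        if max_rate * self.refractory_s >= 0.9:
            raise ValidationError("refractory too long for the configured rates")

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)


def paper_default() -> ScenarioConfig:
    """The shipped default scenario (18 sessions, 10/4/10 min state blocks)."""
    return ScenarioConfig()


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _lobe(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smooth sin^2 lobe supported on [start, end], peak 1 at the midpoint."""
    out = np.zeros_like(t)
    m = (t >= start) & (t <= end)
    out[m] = np.sin(np.pi * (t[m] - start) / (end - start)) ** 2
    return out


def tic_kernel(fs: float, duration_s: float = 0.35,
               latency_s: float = 0.075) -> np.ndarray:
    """Stereotyped tic waveform sampled at ``fs``, normalized to unit p2p.

    One-cycle damped-sinusoid shape: a positive lobe peaking ``latency_s``
    after onset followed by a shallower negative lobe, decaying to zero by
    ``duration_s``.
    """
    t = np.arange(int(round(duration_s * fs))) / fs
    rise = 2.0 * latency_s
    k = 0.55 * _lobe(t, 0.0, rise) - 0.45 * _lobe(t, rise * 0.9, duration_s)
    return k / (k.max() - k.min())


def _asym_lobe(t: np.ndarray, start: float, peak: float, end: float) -> np.ndarray:
    """Asymmetric smooth lobe: sin^2 rise on [start, peak], sin^2 fall on
    [peak, end]; peak 1, C1-continuous."""
    out = np.zeros_like(t)
    m = (t >= start) & (t < peak)
    out[m] = np.sin(0.5 * np.pi * (t[m] - start) / (peak - start)) ** 2
    m = (t >= peak) & (t <= end)
    out[m] = np.cos(0.5 * np.pi * (t[m] - peak) / (end - peak)) ** 2
    return out


def lfp_kernel(fs: float, duration_s: float = 0.54,
               latency_s: float = 0.075) -> np.ndarray:
    """Stereotyped LFP-spike waveform, unit p2p: sharp negative deflection
    peaking ``latency_s`` after onset, then a slow shallow positive lobe
    (fast rise, long tail) whose maximum sits well before the deflection of
    any refractory-respecting successor event."""
    t = np.arange(int(round(duration_s * fs))) / fs
    neg_width = 2.0 * latency_s
    pos_peak = min(0.25, neg_width + 0.3 * (duration_s - neg_width))
    k = -0.78 * _lobe(t, 0.0, neg_width) \
        + 0.22 * _asym_lobe(t, neg_width * 0.95, pos_peak, duration_s)
    return k / (k.max() - k.min())


def burst_kernel(fs: float, latency_s: float = 0.046, ln_sd: float = 0.7,
                 duration_s: float = 0.8) -> np.ndarray:
    """Nonnegative MUA burst-envelope kernel, peak 1 at ``latency_s``.

    Lognormal-shaped bump: fast rise, slow decay; also the event-locked rate
    kernel used for single units.
    """
    t = np.arange(1, int(round(duration_s * fs)) + 1) / fs
    mu = np.log(latency_s) + ln_sd ** 2
    k = np.exp(-((np.log(t) - mu) ** 2) / (2 * ln_sd ** 2))
    return k / k.max()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected events and per-unit locking parameters (the oracle record).

    ``tic_lfp_index[i]`` is the index of the LFP spike that spawned tic *i*
    (or -1 for unpaired tics); the map is injective over paired tics.
    """

    lfp_onset_s: np.ndarray
    lfp_p2p: np.ndarray
    lfp_state: np.ndarray
    tic_onset_s: np.ndarray
    tic_p2p: np.ndarray
    tic_state: np.ndarray
    tic_lfp_index: np.ndarray
    unit_truth: list[dict] = field(default_factory=list)
    session_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        paired = self.tic_lfp_index[self.tic_lfp_index >= 0]
        if paired.size != np.unique(paired).size:
            raise ValidationError("tic->LFP pairing map is not injective")
        for arr in (self.lfp_onset_s, self.tic_onset_s):
            if arr.size and np.any(np.diff(arr) < 0):
                raise ValidationError("ground-truth events unsorted")

    def save(self, prefix: str | Path) -> None:
        """Write LFP/tic event tables as CSV next to ``prefix``."""
        import pandas as pd
        prefix = Path(prefix)
        pd.DataFrame({"onset_s": self.lfp_onset_s, "p2p": self.lfp_p2p,
                      "state": self.lfp_state}).to_csv(
            prefix.with_suffix(".lfp_truth.csv"), index=False)
        pd.DataFrame({"onset_s": self.tic_onset_s, "p2p": self.tic_p2p,
                      "state": self.tic_state, "lfp_index": self.tic_lfp_index}
                     ).to_csv(prefix.with_suffix(".tic_truth.csv"), index=False)


# ---------------------------------------------------------------------------
# state sequence
# ---------------------------------------------------------------------------

def generate_state_sequence(config: ScenarioConfig,
                            rng: np.random.Generator) -> StateAnnotation:
    """Quiet-waking block, transition block (drowsy micro-intervals), sleep
    block optionally fragmented by brief 'other' awakenings."""
    config.validate()
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    if config.quiet_s > 0:
        intervals.append((t, t + config.quiet_s, "quiet_waking"))
        t += config.quiet_s
    if config.transition_s > 0:
        # alternating drowsy micro-intervals; all carry the transition label,
        # total duration preserved exactly
        if config.transition_micro_s > 0:
            n_micro = max(1, int(round(config.transition_s / config.transition_micro_s)))
        else:
            n_micro = 1
        edges = t + config.transition_s * np.linspace(0.0, 1.0, n_micro + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            intervals.append((a, b, "transition"))
        t += config.transition_s
    if config.sleep_s > 0:
        sleep_end = t + config.sleep_s
        n_aw = config.n_awakenings
        if n_aw > 0 and config.awakening_s > 0 and \
                n_aw * config.awakening_s < config.sleep_s * 0.5:
            # awakenings carved out of the sleep block at jittered positions
            centers = t + config.sleep_s * (
                (np.arange(n_aw) + rng.uniform(0.3, 0.7, n_aw)) / (n_aw + 1) + 0.5 / (n_aw + 1))
            centers = np.sort(centers)
            cursor = t
            for c in centers:
                a = np.clip(c - config.awakening_s / 2, cursor, sleep_end)
                b = np.clip(c + config.awakening_s / 2, cursor, sleep_end)
                if a > cursor:
                    intervals.append((cursor, a, "sleep"))
                if b > a:
                    intervals.append((a, b, "other"))
                cursor = b
            if sleep_end > cursor:
                intervals.append((cursor, sleep_end, "sleep"))
        else:
            intervals.append((t, sleep_end, "sleep"))
    ann = StateAnnotation(intervals)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# session-level parameter draws
# ---------------------------------------------------------------------------

def _draw_session_params(config: ScenarioConfig, rng: np.random.Generator) -> dict:
    """Per-session rates and amplitude means, jittered around group means."""
    f_wake = _unit_gain(rng, np.sqrt(np.log1p(config.rate_session_cv["quiet_waking"] ** 2)))
    f_sleep = _unit_gain(rng, np.sqrt(np.log1p(config.rate_session_cv["sleep"] ** 2)))
    g_shared = _unit_gain(rng, config.amp_gain_shared_ln_sd)
    g_tic = g_shared * _unit_gain(rng, config.amp_gain_tic_ln_sd)
    g_lfp = g_shared * _unit_gain(rng, config.amp_gain_lfp_ln_sd)

    lfp_rate = {lbl: config.lfp_rate_per_min[lbl] / 60.0 *
                (f_sleep if lbl == "sleep" else f_wake)
                for lbl in config.lfp_rate_per_min}
    # residual unpaired tic rate so total tic rate hits its own target
    tic_resid = {}
    for lbl in config.tic_rate_per_min:
        if lbl == "sleep":
            continue
        factor = f_wake
        target = config.tic_rate_per_min[lbl] / 60.0 * factor
        tic_resid[lbl] = max(0.0, target - config.pairing_prob[lbl] * lfp_rate[lbl])
    # zero-inflated sleep tics: only some sessions express them
    if rng.random() < config.sleep_tic_session_prob:
        mean_rate = config.tic_rate_per_min["sleep"] / config.sleep_tic_session_prob / 60.0
        sleep_tic_rate = float(_lognormal(rng, mean_rate, config.sleep_tic_rate_cv))
    else:
        sleep_tic_rate = 0.0
    tic_resid["sleep"] = max(
        0.0, sleep_tic_rate - config.pairing_prob["sleep"] * lfp_rate["sleep"])

    tic_amp = {lbl: config.tic_amp_mean[lbl] * g_tic for lbl in config.tic_amp_mean}
    lfp_amp = {lbl: config.lfp_p2p_mean[lbl] * g_lfp for lbl in config.lfp_p2p_mean}
    return {
        "lfp_rate_per_s": lfp_rate, "tic_residual_rate_per_s": tic_resid,
        "tic_amp_mean": tic_amp, "lfp_amp_mean": lfp_amp,
        "rate_factor_wake": float(f_wake), "rate_factor_sleep": float(f_sleep),
        "amp_gain_tic": float(g_tic), "amp_gain_lfp": float(g_lfp),
    }


# ---------------------------------------------------------------------------
# event generation
# ---------------------------------------------------------------------------

def _renewal_times(rng: np.random.Generator, rate: float, start: float, end: float,
                   refractory: float) -> np.ndarray:
    """Refractory Poisson (renewal) process with realized mean rate ``rate``."""
    if rate <= 0 or end <= start:
        return np.empty(0)
    if rate * refractory >= 0.95:
        rate = 0.95 / refractory  # saturate: as dense as the dead time allows
    lam = rate / (1.0 - rate * refractory)
    times = []
    t = start + rng.exponential(1.0 / lam)
    while t < end:
        times.append(t)
        t += refractory + rng.exponential(1.0 / lam)
    return np.asarray(times)


def _renewal_on_free_time(rng: np.random.Generator, rate: float, start: float,
                          end: float, blocked_iv: list[tuple[float, float]],
                          refractory: float) -> np.ndarray:
    """Renewal process over the part of [start, end) outside every blocked
    interval, with the rate referred to the *whole* interval (compensated for
    the occupied measure)."""
    if rate <= 0 or end <= start:
        return np.empty(0)
    # free sub-intervals
    free: list[tuple[float, float]] = []
    cursor = start
    for a, b in sorted(blocked_iv):
        if a > cursor:
            free.append((cursor, min(a, end)))
        cursor = max(cursor, min(max(b, cursor), end))
    if cursor < end:
        free.append((cursor, end))
    total_free = sum(b - a for a, b in free)
    if total_free <= 0:
        return np.empty(0)
    eff_rate = rate * (end - start) / total_free
    if eff_rate * refractory >= 1.0:
        eff_rate = 0.99 / refractory  # saturated: as dense as the refractory allows
    # draw on the concatenated free measure, then map back
    virt = _renewal_times(rng, eff_rate, 0.0, total_free, refractory)
    out = []
    offsets = np.cumsum([0.0] + [b - a for a, b in free])
    for v in virt:
        k = int(np.searchsorted(offsets, v, side="right") - 1)
        if k < len(free):
            out.append(free[k][0] + (v - offsets[k]))
    return np.asarray(out)


def _transition_amp_mean(t: np.ndarray, t_start: float, duration: float,
                         quiet_mean: float, sleep_mean: float) -> np.ndarray:
    """Tic-amplitude mean decays exponentially through the transition block,
    time constant = one third of the block duration."""
    tau = duration / 3.0 if duration > 0 else 1.0
    return sleep_mean + (quiet_mean - sleep_mean) * np.exp(-(t - t_start) / tau)


def generate_events(states: StateAnnotation, config: ScenarioConfig,
                    rng: np.random.Generator,
                    session_params: dict | None = None) -> GroundTruth:
    """Draw LFP-spike and tic events over an annotated session.

    LFP spikes: per-interval refractory Poisson process.  Tics: each LFP
    spike spawns one tic with state-dependent probability (onset lagging the
    LFP onset by ``tic_lag_s``), plus residual unpaired tics.  Amplitudes are
    lognormal; during the transition block the tic-amplitude mean decays
    exponentially toward the sleep mean, which is what makes the transition
    amplitude CV high.
    """
    config.validate()
    params = session_params or _draw_session_params(config, rng)
    grid = 1.0 / config.lfp_fs

    trans_iv = states.intervals_of("transition")
    trans_start = trans_iv[0][0] if trans_iv else 0.0
    trans_total = sum(e - s for s, e in trans_iv)
    quiet_amp = params["tic_amp_mean"]["quiet_waking"]
    sleep_amp = params["tic_amp_mean"]["sleep"]

    def tic_amp_mean_at(t: np.ndarray, label: str) -> np.ndarray:
        if label == "transition":
            return _transition_amp_mean(t, trans_start, trans_total, quiet_amp, sleep_amp)
        return np.full(np.shape(t), params["tic_amp_mean"].get(label, quiet_amp))

    lfp_onsets, lfp_amps, lfp_states = [], [], []
    tic_onsets, tic_amps, tic_states, tic_pair = [], [], [], []

    for start, end, label in states.intervals:
        lrate = params["lfp_rate_per_s"].get(label, 0.0)
        onsets = np.round(_renewal_times(rng, lrate, start, end, config.refractory_s)
                          / grid) * grid
        onsets = onsets[(onsets >= start) & (onsets < end)]
        amps = _lognormal(rng, 1.0, config.lfp_p2p_cv.get(label, 0.24), onsets.size) \
            * params["lfp_amp_mean"].get(label, params["lfp_amp_mean"]["quiet_waking"])
        idx0 = len(lfp_onsets)
        lfp_onsets.extend(onsets)
        lfp_amps.extend(np.atleast_1d(amps))
        lfp_states.extend([label] * onsets.size)

        # paired tics
        p = config.pairing_prob.get(label, 0.0)
        if p > 0 and onsets.size:
            spawned = rng.random(onsets.size) < p
            t_tic = onsets[spawned] + config.tic_lag_s
            means = tic_amp_mean_at(t_tic, label)
            a_tic = _lognormal(rng, 1.0, config.tic_amp_cv.get(label, 0.45), t_tic.size) * means
            tic_onsets.extend(t_tic)
            tic_amps.extend(np.atleast_1d(a_tic))
            tic_states.extend(np.atleast_1d(states.label_at(t_tic)))
            tic_pair.extend(idx0 + np.flatnonzero(spawned))

        # residual unpaired tics: tics whose field-potential correlate is not
        # detectable.  Placed away from existing tics (one refractory) and
        # away from LFP-spike co-occurrence windows -- by construction they
        # have no detected LFP counterpart -- at a rate compensated for the
        # occupied measure so the total tic rate stays on target.
        rrate = params["tic_residual_rate_per_s"].get(label, 0.0)
        blocked = [(t - config.refractory_s, t + config.refractory_s)
                   for t in tic_onsets if start - 1.0 <= t < end + 1.0]
        blocked += [(t - 0.1, t + 0.6) for t in lfp_onsets
                    if start - 1.0 <= t < end + 1.0]
        extra = _renewal_on_free_time(rng, rrate, start, end, blocked,
                                      config.refractory_s)
        extra = np.round(extra / grid) * grid
        extra = extra[(extra >= start) & (extra < end)]
        if extra.size:
            means = tic_amp_mean_at(extra, label)
            a_ex = _lognormal(rng, 1.0, config.tic_amp_cv.get(label, 0.45), extra.size) * means
            tic_onsets.extend(extra)
            tic_amps.extend(np.atleast_1d(a_ex))
            tic_states.extend([label] * extra.size)
            tic_pair.extend([-1] * extra.size)

    order = np.argsort(np.asarray(tic_onsets)) if tic_onsets else np.empty(0, int)
    gt = GroundTruth(
        lfp_onset_s=np.asarray(lfp_onsets), lfp_p2p=np.asarray(lfp_amps),
        lfp_state=np.asarray(lfp_states, dtype=object),
        tic_onset_s=np.asarray(tic_onsets)[order],
        tic_p2p=np.asarray(tic_amps)[order],
        tic_state=np.asarray(tic_states, dtype=object)[order],
        tic_lfp_index=np.asarray(tic_pair, dtype=int)[order] if tic_onsets else np.empty(0, int),
        session_params=params,
    )
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_kernels(signal: np.ndarray, fs: float, onsets: np.ndarray,
                 amps: np.ndarray, kernel: np.ndarray) -> None:
    """Superpose amplitude-scaled kernels at the given onsets, in place."""
    n = signal.size
    for t, a in zip(onsets, amps):
        i0 = int(round(t * fs))
        if i0 >= n:
            continue
        i1 = min(i0 + kernel.size, n)
        if i1 <= i0:
            continue
        signal[i0:i1] += a * kernel[:i1 - i0]


def render_gyro(truth: GroundTruth, states: StateAnnotation, config: ScenarioConfig,
                rng: np.random.Generator) -> np.ndarray:
    """3-channel gyroscope trace; tics rendered on the x channel only.

    Overlapping tics superpose linearly; with noise SD 0 the measured p2p of
    an isolated tic equals its configured amplitude exactly (the sampled
    kernel is normalized to unit p2p on the rendering grid).
    """
    n = int(round(states.end_s * config.gyro_fs))
    kernel = tic_kernel(config.gyro_fs, config.gyro_kernel_s, config.gyro_kernel_latency_s)
    if kernel.size > n:
        raise ValidationError("tic kernel longer than session")
    gyro = rng.normal(0.0, config.gyro_noise_sd, size=(n, 3))
    _add_kernels(gyro[:, 0], config.gyro_fs, truth.tic_onset_s, truth.tic_p2p, kernel)
    return gyro


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                        f_hi: float, pink: bool = True) -> np.ndarray:
    """Noise confined below ``f_hi``; 1/f amplitude weighting when ``pink``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    w = np.zeros_like(freqs)
    band = (freqs > 0) & (freqs <= f_hi)
    w[band] = 1.0 / np.sqrt(np.maximum(freqs[band], 1.0)) if pink else 1.0
    x = np.fft.irfft(spec * w, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def render_lfp(truth: GroundTruth, states: StateAnnotation, config: ScenarioConfig,
               rng: np.random.Generator, fs: float | None = None) -> np.ndarray:
    """Field-potential trace(s) at ``fs`` (default ``config.lfp_fs``):
    per-event biphasic kernels plus pink noise confined below 100 Hz."""
    fs = fs or config.lfp_fs
    n = int(round(states.end_s * fs))
    kernel = lfp_kernel(fs, config.lfp_kernel_s, config.lfp_kernel_latency_s)
    if kernel.size > n:
        raise ValidationError("LFP kernel longer than session")
    out = np.empty((config.n_electrodes, n))
    for e in range(config.n_electrodes):
        trace = _band_limited_noise(rng, n, fs, config.lfp_noise_sd, 100.0)
        _add_kernels(trace, fs, truth.lfp_onset_s, truth.lfp_p2p, kernel)
        out[e] = trace
    return out


def _burst_gain_track(truth: GroundTruth, states: StateAnnotation,
                      config: ScenarioConfig, fs: float, n: int) -> np.ndarray:
    """Multiplicative MUA envelope track 1 + gain(state) * burst kernel."""
    kernel = burst_kernel(fs, config.mua_kernel_latency_s, config.mua_kernel_ln_sd)
    track = np.zeros(n)
    gains = np.array([config.mua_gain.get(s, 0.0) for s in truth.lfp_state])
    _add_kernels(track, fs, truth.lfp_onset_s, gains, kernel)
    return 1.0 + track


def render_wideband(truth: GroundTruth, states: StateAnnotation, config: ScenarioConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Wideband trace(s): LFP component (<100 Hz) plus MUA component --
    band-limited >300 Hz noise amplitude-modulated by an LFP-spike-locked
    burst envelope with state-dependent gain."""
    from scipy.signal import butter, sosfiltfilt
    fs = config.wideband_fs
    if fs < 2 * 300.0:
        raise ValidationError("wideband sampling rate too low for the MUA band")
    n = int(round(states.end_s * fs))
    lfp_part = render_lfp(truth, states, config, rng, fs=fs)
    sos = butter(4, 300.0, btype="highpass", fs=fs, output="sos")
    gain_track = _burst_gain_track(truth, states, config, fs, n)
    out = np.empty((config.n_electrodes, n))
    for e in range(config.n_electrodes):
        mua = sosfiltfilt(sos, rng.standard_normal(n))
        mua *= config.mua_noise_sd / mua.std()
        out[e] = lfp_part[e] + mua * gain_track
    return out


# ---------------------------------------------------------------------------
# single units
# ---------------------------------------------------------------------------

def _synth_waveform(fs: float, trough_to_peak_ms: float) -> np.ndarray:
    """Synthesized mean spike waveform: narrow (FSI) or wide (SPN)."""
    t = np.arange(int(round(0.003 * fs))) / fs * 1000.0  # ms
    t_trough = 0.5
    t_peak = t_trough + trough_to_peak_ms
    w = -np.exp(-((t - t_trough) ** 2) / (2 * 0.08 ** 2)) \
        + 0.45 * np.exp(-((t - t_peak) ** 2) / (2 * (0.12 + 0.25 * trough_to_peak_ms) ** 2))
    return w


def _sample_from_kernel(rng: np.random.Generator, kernel: np.ndarray, fs: float,
                        n: int) -> np.ndarray:
    """Draw ``n`` latencies from the normalized kernel density."""
    cdf = np.cumsum(kernel)
    cdf /= cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u)
    return (idx + rng.random(n)) / fs


def render_units(truth: GroundTruth, states: StateAnnotation, config: ScenarioConfig,
                 rng: np.random.Generator) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains for the configured SPN/FSI population.

    Each unit's rate is baseline(type, state) plus an LFP-spike-locked
    Gaussian burst kernel scaled by a state-dependent locking gain.  The
    configured per-state rates are *total* rates: the baseline is the
    configured rate minus the expected event-locked contribution, so the
    recovered firing rates land on the configured values.  Because the rate
    is a sum of nonnegative components, the train is simulated exactly by
    superposing a piecewise-homogeneous baseline process with per-event
    kernel-distributed spikes (no thinning, no rate clipping ever triggered).
    """
    duration = states.end_s
    fs_k = 1000.0
    alt_latency = config.unit_kernel_latency_s + 0.15   # shifted-pattern variant
    t_k = np.arange(int(round((alt_latency + 4 * config.unit_kernel_sd_s) * fs_k))) / fs_k
    kern = np.exp(-((t_k - config.unit_kernel_latency_s) ** 2)
                  / (2 * config.unit_kernel_sd_s ** 2))
    kern_alt = np.exp(-((t_k - alt_latency) ** 2) / (2 * config.unit_kernel_sd_s ** 2))
    k_int = kern.sum() / fs_k          # integral of the unit-peak kernel (s)
    k_alt_int = kern_alt.sum() / fs_k
    # empirical per-state LFP-spike rate of this session (locked contribution)
    lfp_rate_state: dict[str, float] = {}
    for lbl in set(truth.lfp_state):
        dur_l = states.duration_of(str(lbl))
        if dur_l > 0:
            lfp_rate_state[str(lbl)] = float((truth.lfp_state == lbl).sum()) / dur_l

    units: list[SpikeTrain] = []
    specs = [("SPN", config.spn_rate, config.spn_lock_mag, 0.70, config.n_spn),
             ("FSI", config.fsi_rate, config.fsi_lock_mag, 0.25, config.n_fsi)]
    for utype, base_rates, lock_mags, width_ms, count in specs:
        for j in range(count):
            # median-1 spread for baseline rates (population values are
            # medians), mean-1 spread for locking magnitudes (reported as means)
            rate_gain = float(rng.lognormal(0.0, config.unit_rate_ln_sd))
            mag_gain = float(_lognormal(rng, 1.0, config.unit_mag_cv))
            lost = rng.random() < config.lock_lost_prob[utype]
            diff_pattern = rng.random() < config.lock_pattern_change_prob
            spikes = []
            for start, end, label in states.intervals:
                total = base_rates.get(label, base_rates["quiet_waking"]) * rate_gain
                mag_l = lock_mags.get(label, 0.0) * mag_gain
                if label == "sleep" and lost:
                    mag_l = 0.0
                locked = mag_l * k_int * lfp_rate_state.get(label, 0.0)
                lam = max(total - locked, 0.05 * total)
                n_base = rng.poisson(lam * (end - start))
                spikes.append(rng.uniform(start, end, n_base))
            # event-locked spikes
            for t_ev, st_ev in zip(truth.lfp_onset_s, truth.lfp_state):
                mag = lock_mags.get(st_ev, 0.0) * mag_gain
                use_alt = False
                if st_ev == "sleep":
                    if lost:
                        mag = 0.0
                    elif diff_pattern:
                        use_alt = True
                if mag <= 0:
                    continue
                ki = k_alt_int if use_alt else k_int
                n_ev = rng.poisson(mag * ki)
                if n_ev:
                    lat = _sample_from_kernel(rng, kern_alt if use_alt else kern, fs_k, n_ev)
                    spikes.append(t_ev + lat)
            t_all = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
            t_all = t_all[(t_all >= 0) & (t_all < duration)]
            # enforce strict ordering (duplicates possible after merging)
            if t_all.size > 1:
                eps = 1e-6
                for i in range(1, t_all.size):
                    if t_all[i] <= t_all[i - 1]:
                        t_all[i] = t_all[i - 1] + eps
            units.append(SpikeTrain(
                unit_id=f"{utype.lower()}{j:02d}",
                spike_times_s=t_all,
                mean_waveform=_synth_waveform(config.waveform_fs, width_ms),
                waveform_fs=config.waveform_fs,
                putative_type="unclassified",
            ))
            truth.unit_truth.append({
                "unit_id": units[-1].unit_id, "true_type": utype,
                "rate_gain": rate_gain, "mag_gain": mag_gain,
                "wake_mag": lock_mags["quiet_waking"] * mag_gain,
                "sleep_mag": 0.0 if lost else lock_mags["sleep"] * mag_gain,
                "lost": bool(lost), "diff_pattern": bool(diff_pattern),
            })
    return units


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def generate_session(config: ScenarioConfig, seed_or_rng: int | np.random.Generator,
                     session_id: str = "synthetic-000",
                     ) -> tuple[SessionRecording, GroundTruth]:
    """Generate one full synthetic session; deterministic given (config, seed)."""
    config.validate()
    if isinstance(seed_or_rng, np.random.Generator):
        rng = seed_or_rng
    else:
        rng = np.random.default_rng(seed_or_rng)
    states = generate_state_sequence(config, rng)
    truth = generate_events(states, config, rng)
    gyro = render_gyro(truth, states, config, rng)
    if config.render_wideband:
        wideband = render_wideband(truth, states, config, rng)
        lfp_sig, lfp_fs = None, 0.0
        wb_fs = config.wideband_fs
    else:
        wideband, wb_fs = None, 0.0
        lfp_sig = render_lfp(truth, states, config, rng)
        lfp_fs = config.lfp_fs
    units = render_units(truth, states, config, rng)
    session = SessionRecording(
        session_id=session_id,
        gyro=gyro, gyro_fs=config.gyro_fs,
        wideband=wideband, wideband_fs=wb_fs,
        lfp=lfp_sig, lfp_fs=lfp_fs,
        units=units, states=states,
    )
    session.validate()
    return session, truth


def generate_study(config: ScenarioConfig,
                   seed: int | None = None) -> Iterator[tuple[SessionRecording, GroundTruth]]:
    """Yield ``config.n_sessions`` sessions with distinct per-session sub-seeds."""
    root = np.random.SeedSequence([config.seed if seed is None else seed])
    for i, child in enumerate(root.spawn(config.n_sessions)):
        rng = np.random.default_rng(child)
        yield generate_session(config, rng, session_id=f"synthetic-{i:03d}")
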