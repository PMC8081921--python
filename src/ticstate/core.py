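"""Shared data model, time conventions and session I/O.

Time convention: seconds from session start (t0 = 0); all state intervals are
half-open ``[start, end)``.  A session bundles the recorded modalities of one
sleep-wake cycle: the 3-axis head gyroscope (deg/s), one or more striatal
extracellular voltage traces (uV) -- either wideband or an already low-passed
local field potential (LFP) -- sorted single-unit spike trains, and a manual
behavioral-state annotation track.

On disk a session is one HDF5 file with a group per modality, plus plain-text
sidecars (BED-like TSV for state intervals, CSV for event tables) for
interoperability with generic tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: the four analysis-relevant behavioral-state labels
STATE_LABELS = ("quiet_waking", "transition", "sleep", "other")


class ValidationError(ValueError):
    """A container invariant does not hold."""


class MissingModalityError(KeyError):
    """A requested/required modality is absent from a session file."""


# ---------------------------------------------------------------------------
# state annotations
# ---------------------------------------------------------------------------

@dataclass
class StateAnnotation:
    """Ordered, non-overlapping labeled time intervals ``[start, end)``.

    ``intervals`` is a list of ``(start_s, end_s, label)`` tuples with labels
    drawn from :data:`STATE_LABELS`.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b), str(lbl)) for a, b, lbl in self.intervals]

    def validate(self, duration_s: float | None = None) -> None:
        prev_end = -np.inf
        for start, end, label in self.intervals:
            if label not in STATE_LABELS:
                raise ValidationError(f"unknown state label {label!r}")
            if not start < end:
                raise ValidationError(f"empty or inverted interval ({start}, {end})")
            if start < prev_end:
                raise ValidationError("intervals overlap or are unsorted")
            prev_end = end
        if self.intervals and self.intervals[0][0] < 0:
            raise ValidationError("interval starts before session start")
        if duration_s is not None and self.intervals:
            if self.intervals[-1][1] > duration_s + 1e-9:
                raise ValidationError("annotations extend past session end")

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def duration_of(self, label: str) -> float:
        """Total labeled seconds for one label."""
        if label not in STATE_LABELS:
            raise ValidationError(f"unknown state label {label!r}")
        return float(sum(e - s for s, e, lbl in self.intervals if lbl == label))

    def intervals_of(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lbl in self.intervals if lbl == label]

    def label_at(self, t: float | np.ndarray):
        """Label(s) at time(s) ``t``; ``None``/'' where unannotated.

        Boundary times belong to the later interval (half-open convention).
        """
        scalar = np.isscalar(t)
        times = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(times.shape, "", dtype=object)
        for start, end, label in self.intervals:
            out[(times >= start) & (times < end)] = label
        if scalar:
            return out[0] or None
        return out


def state_mask(states: StateAnnotation, label: str, fs: float, n_samples: int) -> np.ndarray:
    """Boolean mask, true exactly for samples whose time lies in a ``[start, end)``
    interval carrying ``label``.

    Sample *i* has time ``i / fs``; adjacent intervals sharing a boundary assign
    the boundary sample to the later interval.
    """
    if fs <= 0:
        raise ValidationError("fs must be > 0")
    if label not in STATE_LABELS:
        raise ValidationError(f"unknown state label {label!r}")
    mask = np.zeros(int(n_samples), dtype=bool)
    for start, end, lbl in states.intervals:
        if lbl != label:
            continue
        i0 = int(np.ceil(start * fs - 1e-9))
        i1 = int(np.ceil(end * fs - 1e-9))
        mask[max(i0, 0):max(min(i1, n_samples), 0)] = True
    return mask


# ---------------------------------------------------------------------------
# spike trains and events
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """One sorted unit: strictly increasing spike times plus a mean waveform."""

    unit_id: str
    spike_times_s: np.ndarray
    mean_waveform: np.ndarray | None = None
    waveform_fs: float | None = None
    putative_type: str = "unclassified"  # {SPN, FSI, unclassified}

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)

    def validate(self, duration_s: float | None = None) -> None:
        t = self.spike_times_s
        if t.ndim != 1:
            raise ValidationError("spike times must be 1-D")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not strictly increasing")
        if t.size and (t[0] < 0 or (duration_s is not None and t[-1] > duration_s + 1e-9)):
            raise ValidationError(f"unit {self.unit_id}: spike times outside session")
        if self.putative_type not in ("SPN", "FSI", "unclassified"):
            raise ValidationError(f"unknown putative_type {self.putative_type!r}")


@dataclass
class EventSeries:
    """Detected (or injected ground-truth) events of one kind.

    ``kind`` is ``"tic"`` (gyroscope) or ``"lfp_spike"`` (field potential);
    amplitude is the peak-to-peak delta measured inside the snippet window
    ``(pre_s, post_s)`` around onset.
    """

    kind: str
    onset_s: np.ndarray
    peak_s: np.ndarray
    p2p_amplitude: np.ndarray
    state: np.ndarray  # state label per event ('' where unannotated)
    window_s: tuple[float, float] = (0.1, 0.6)

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.peak_s = np.asarray(self.peak_s, dtype=float)
        self.p2p_amplitude = np.asarray(self.p2p_amplitude, dtype=float)
        self.state = np.asarray(self.state, dtype=object)

    def __len__(self) -> int:
        return self.onset_s.size

    def validate(self) -> None:
        if self.kind not in ("tic", "lfp_spike"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        n = len(self)
        for name in ("peak_s", "p2p_amplitude", "state"):
            if getattr(self, name).size != n:
                raise ValidationError("event fields have inconsistent lengths")
        if n and not np.all(np.diff(self.onset_s) >= 0):
            raise ValidationError("events not sorted by onset")
        if np.any(self.p2p_amplitude < 0):
            raise ValidationError("negative peak-to-peak amplitude")
        if n and np.any(self.peak_s < self.onset_s - 1e-9):
            raise ValidationError("peak precedes onset")
        if n and np.any(self.peak_s > self.onset_s + self.window_s[1] + 1e-9):
            raise ValidationError("peak outside snippet window")

    def select(self, mask: np.ndarray) -> "EventSeries":
        return EventSeries(self.kind, self.onset_s[mask], self.peak_s[mask],
                           self.p2p_amplitude[mask], self.state[mask], self.window_s)

    def in_state(self, label: str) -> "EventSeries":
        return self.select(np.asarray([s == label for s in self.state], dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onset_s, "peak_s": self.peak_s,
            "p2p_amplitude": self.p2p_amplitude,
            "state": [s or "" for s in self.state],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str,
                 window_s: tuple[float, float] = (0.1, 0.6)) -> "EventSeries":
        df = pd.read_csv(path)
        state = df["state"].fillna("").astype(object).to_numpy() if "state" in df else \
            np.full(len(df), "", dtype=object)
        return cls(kind, df["onset_s"].to_numpy(), df["peak_s"].to_numpy(),
                   df["p2p_amplitude"].to_numpy(), state, window_s)


# ---------------------------------------------------------------------------
# peri-event histogram container
# ---------------------------------------------------------------------------

@dataclass
class Plth:
    """Peri-event histogram / average.

    ``values`` holds the per-bin mean over events, in the units of the aligned
    signal (spikes/s for spike-train histograms).  Bin *i* covers
    ``[-pre + i*bin, -pre + (i+1)*bin)`` relative to event onset; bin centers
    come from :attr:`times`.
    """

    values: np.ndarray
    window_s: tuple[float, float]            # (pre, post), both positive
    n_events: int
    bin_width_s: float = 0.001
    smoothing_sd_s: float = 0.010
    baseline_window_s: tuple[float, float] = (-0.2, -0.15)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def validate(self) -> None:
        pre, post = self.window_s
        n_bins = int(round((pre + post) / self.bin_width_s))
        if self.values.size != n_bins:
            raise ValidationError("bin count inconsistent with window/bin width")
        if self.n_events < 1:
            raise ValidationError("PLTH needs at least one event")
        if self.smoothing_sd_s < 0:
            raise ValidationError("smoothing SD must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """Bin-center times relative to onset (s)."""
        pre, post = self.window_s
        n = self.values.size
        return -pre + (np.arange(n) + 0.5) * self.bin_width_s

    @property
    def onset_index(self) -> int:
        return int(round(self.window_s[0] / self.bin_width_s))

    def baseline_slice(self) -> slice:
        b0, b1 = self.baseline_window_s
        pre = self.window_s[0]
        return slice(int(round((b0 + pre) / self.bin_width_s)),
                     int(round((b1 + pre) / self.bin_width_s)))


# ---------------------------------------------------------------------------
# the session container
# ---------------------------------------------------------------------------

@dataclass
class SessionRecording:
    """All signals, spike trains and annotations of one recording session."""

    session_id: str
    gyro: np.ndarray | None = None           # (n, 3) deg/s
    gyro_fs: float = 0.0
    wideband: np.ndarray | None = None       # (n_electrodes, n) uV
    wideband_fs: float = 0.0
    lfp: np.ndarray | None = None            # (n_electrodes, n) uV, < 100 Hz
    lfp_fs: float = 0.0
    units: list[SpikeTrain] = field(default_factory=list)
    states: StateAnnotation = field(default_factory=StateAnnotation)

    t0: float = 0.0  # session clock origin, always 0 by convention

    @property
    def duration_s(self) -> float:
        durs = [d for d in (
            self.gyro.shape[0] / self.gyro_fs if self.gyro is not None else None,
            self.wideband.shape[1] / self.wideband_fs if self.wideband is not None else None,
            self.lfp.shape[1] / self.lfp_fs if self.lfp is not None else None,
        ) if d is not None]
        if durs:
            return float(durs[0])
        return self.states.end_s

    def validate(self) -> None:
        durs: list[float] = []
        periods: list[float] = []
        if self.gyro is not None:
            if self.gyro_fs <= 0:
                raise ValidationError("gyro sampling rate must be > 0")
            if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
                raise ValidationError("gyro must be (n_samples, 3)")
            durs.append(self.gyro.shape[0] / self.gyro_fs)
            periods.append(1.0 / self.gyro_fs)
        for name, sig, fs in (("wideband", self.wideband, self.wideband_fs),
                              ("lfp", self.lfp, self.lfp_fs)):
            if sig is not None:
                if fs <= 0:
                    raise ValidationError(f"{name} sampling rate must be > 0")
                if sig.ndim != 2:
                    raise ValidationError(f"{name} must be (n_electrodes, n_samples)")
                durs.append(sig.shape[1] / fs)
                periods.append(1.0 / fs)
        if durs:
            if max(durs) - min(durs) > max(periods) + 1e-9:
                raise ValidationError("signal durations disagree by more than one sample period")
        dur = self.duration_s
        self.states.validate(duration_s=dur if durs else None)
        for u in self.units:
            u.validate(duration_s=dur if durs else None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write a validated session to one HDF5 container."""
    session.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["t0"] = session.t0
        if session.gyro is not None:
            g = f.create_group("gyro")
            g.create_dataset("data", data=session.gyro)
            g.attrs["fs"] = session.gyro_fs
        for name, sig, fs in (("wideband", session.wideband, session.wideband_fs),
                              ("lfp", session.lfp, session.lfp_fs)):
            if sig is not None:
                g = f.create_group(name)
                g.create_dataset("data", data=sig)
                g.attrs["fs"] = fs
        ug = f.create_group("units")
        for u in session.units:
            gu = ug.create_group(u.unit_id)
            gu.create_dataset("spike_times_s", data=u.spike_times_s)
            gu.attrs["putative_type"] = u.putative_type
            if u.mean_waveform is not None:
                gu.create_dataset("mean_waveform", data=u.mean_waveform)
                gu.attrs["waveform_fs"] = u.waveform_fs if u.waveform_fs else 0.0
        sg = f.create_group("states")
        iv = session.states.intervals
        sg.create_dataset("start_s", data=np.array([i[0] for i in iv], dtype=float))
        sg.create_dataset("end_s", data=np.array([i[1] for i in iv], dtype=float))
        sg.create_dataset("label", data=np.array([i[2] for i in iv], dtype=object), dtype=_STR)


def read_session(path: str | Path, require: Sequence[str] = ()) -> SessionRecording:
    """Read a session container written by :func:`write_session` or the generator.

    ``require`` names modalities ("gyro", "wideband", "lfp", "units") that must
    be present; a missing one raises :class:`MissingModalityError` naming it.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        kw: dict = {"session_id": str(f.attrs["session_id"]), "t0": float(f.attrs.get("t0", 0.0))}
        if "gyro" in f:
            kw["gyro"] = f["gyro/data"][()]
            kw["gyro_fs"] = float(f["gyro"].attrs["fs"])
        for name in ("wideband", "lfp"):
            if name in f:
                kw[name] = f[f"{name}/data"][()]
                kw[f"{name}_fs"] = float(f[name].attrs["fs"])
        units = []
        if "units" in f:
            for uid in sorted(f["units"]):
                gu = f["units"][uid]
                units.append(SpikeTrain(
                    unit_id=uid,
                    spike_times_s=gu["spike_times_s"][()],
                    mean_waveform=gu["mean_waveform"][()] if "mean_waveform" in gu else None,
                    waveform_fs=float(gu.attrs["waveform_fs"]) if "mean_waveform" in gu else None,
                    putative_type=str(gu.attrs.get("putative_type", "unclassified")),
                ))
        kw["units"] = units
        if "states" in f:
            starts = f["states/start_s"][()]
            ends = f["states/end_s"][()]
            labels = [lbl.decode() if isinstance(lbl, bytes) else str(lbl)
                      for lbl in f["states/label"][()]]
            kw["states"] = StateAnnotation(list(zip(starts, ends, labels)))
    for name in require:
        present = kw.get(name) is not None and (name != "units" or len(kw["units"]))
        if not present:
            raise MissingModalityError(f"modality absent: {name}")
    session = SessionRecording(**kw)
    session.validate()
    return session


def write_states_tsv(states: StateAnnotation, path: str | Path) -> None:
    """Export annotations as a BED-like 3-column TSV (start_s, end_s, label)."""
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for start, end, label in states.intervals:
            fh.write(f"{start:.6f}\t{end:.6f}\t{label}\n")


def read_states_tsv(path: str | Path) -> StateAnnotation:
    df = pd.read_csv(path, sep="\t")
    ann = StateAnnotation(list(zip(df["start_s"], df["end_s"], df["label"])))
    ann.validate()
    return ann
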