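"""Core data containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "EpochSet", "EventSeries", "LfpTrace"]


def _as_sorted_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float).ravel()
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    return t


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, with shank and optional HD label."""

    unit_id: int
    times: np.ndarray
    shank_id: int = 0
    kind: str | None = None  # "hd" | "nonhd" | None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times not sorted")
        self.times = t

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def restrict(self, epochs: "EpochSet") -> np.ndarray:
        """Spike times falling inside `epochs` (half-open intervals)."""
        return self.times[epochs.contains(self.times)]


@dataclass
class EpochSet:
    """Sorted, non-overlapping labeled intervals (seconds)."""

    label: str
    intervals: np.ndarray  # (n, 2)

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            bad = np.flatnonzero(iv[:, 1] <= iv[:, 0])
            if bad.size:
                raise ValueError(f"epochs '{self.label}': non-positive duration at rows {bad.tolist()}")
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            overlap = np.flatnonzero(iv[1:, 0] < iv[:-1, 1])
            if overlap.size:
                rows = [(int(i), int(i + 1)) for i in overlap]
                raise ValueError(f"epochs '{self.label}': overlapping intervals at rows {rows}")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    def total_duration(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if len(self) else 0.0

    def contains(self, times) -> np.ndarray:
        """Boolean mask of times inside any interval (half-open [s, e))."""
        t = np.asarray(times, dtype=float)
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        valid = np.flatnonzero(ok)
        inside.flat[valid] = t.flat[valid] < self.intervals[idx.flat[valid], 1]
        return inside

    def intersect(self, other: "EpochSet", label: str | None = None) -> "EpochSet":
        out = []
        for s0, e0 in self.intervals:
            for s1, e1 in other.intervals:
                s, e = max(s0, s1), min(e0, e1)
                if e > s:
                    out.append((s, e))
        return EpochSet(label or self.label, np.array(out, float).reshape(-1, 2))


@dataclass
class EventSeries:
    """Event intervals with a peak time; kind 'swr' or 'baseline'."""

    kind: str
    start_s: np.ndarray
    peak_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.start_s, dtype=float).ravel()
        p = np.asarray(self.peak_s, dtype=float).ravel()
        e = np.asarray(self.end_s, dtype=float).ravel()
        if not (s.size == p.size == e.size):
            raise ValueError("start/peak/end must have equal length")
        if s.size:
            if np.any(s > p + 1e-12) or np.any(p > e + 1e-12):
                raise ValueError("events must satisfy start <= peak <= end")
            order = np.argsort(p)
            s, p, e = s[order], p[order], e[order]
        self.start_s, self.peak_s, self.end_s = s, p, e

    def __len__(self) -> int:
        return self.peak_s.size

    @property
    def durations(self) -> np.ndarray:
        return self.end_s - self.start_s

    @classmethod
    def from_peaks(cls, kind: str, peaks) -> "EventSeries":
        p = np.asarray(peaks, dtype=float)
        return cls(kind, p.copy(), p.copy(), p.copy())


@dataclass
class LfpTrace:
    """One LFP channel: uniformly sampled signed amplitudes."""

    fs_hz: float
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise ValueError("LFP must contain at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.samples.size) / self.fs_hz

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs_hz

    def sample_index(self, t) -> np.ndarray:
        idx = np.round((np.asarray(t, float) - self.start_s) * self.fs_hz).astype(int)
        return np.clip(idx, 0, self.samples.size - 1)
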