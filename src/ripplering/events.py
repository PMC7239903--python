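"""Session file I/O and event detection (SWRs, UP/DOWN states, baselines).

File formats: a JSON manifest naming a spikes TSV (unit_id, shank_id,
time_s), an epochs TSV (label, start_s, end_s), an optional events TSV
(start_s, peak_s, end_s) and an optional LFP file (int16 little-endian
binary with scale metadata, or one-column TSV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import EpochSet, EventSeries, LfpTrace, SpikeTrain
from .rng import stream

__all__ = [
    "SessionData",
    "read_session",
    "write_events",
    "write_epochs",
    "detect_swr",
    "detect_up_down",
    "epoch_normalized_event_rate",
    "sample_baseline_events",
]


@dataclass
class SessionData:
    units: list[SpikeTrain]
    epochs: dict[str, EpochSet]
    lfp: LfpTrace | None
    events: EventSeries | None
    manifest: dict


def read_session(manifest_path) -> SessionData:
    """Load a session from its manifest; validates sortedness and epoch
    consistency on the way in."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    files = manifest["files"]

    kinds = {u["unit_id"]: u.get("kind") for u in manifest.get("units", [])}
    spikes = pd.read_csv(root / files["spikes"], sep="\t")
    units = []
    if len(spikes):
        for uid, grp in spikes.groupby("unit_id", sort=True):
            t = grp["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"unit {uid}: spike times not sorted in file")
            units.append(
                SpikeTrain(
                    unit_id=int(uid),
                    times=t,
                    shank_id=int(grp["shank_id"].iloc[0]),
                    kind=kinds.get(int(uid)),
                )
            )

    epochs_df = pd.read_csv(root / files["epochs"], sep="\t")
    epochs = {
        str(label): EpochSet(str(label), grp[["start_s", "end_s"]].to_numpy(dtype=float))
        for label, grp in epochs_df.groupby("label", sort=True)
    }

    events = None
    if "events" in files and (root / files["events"]).exists():
        ev = pd.read_csv(root / files["events"], sep="\t")
        events = EventSeries(
            "swr",
            ev["start_s"].to_numpy(float),
            ev["peak_s"].to_numpy(float),
            ev["end_s"].to_numpy(float),
        )

    lfp = None
    if "lfp" in files:
        meta = manifest.get("lfp", {})
        path = root / files["lfp"]
        if meta.get("format") == "int16":
            raw = np.frombuffer(path.read_bytes(), dtype="<i2").astype(float)
            samples = raw * float(meta.get("scale", 1.0))
        else:
            samples = pd.read_csv(path, sep="\t")["sample"].to_numpy(float)
        lfp = LfpTrace(fs_hz=float(meta["fs_hz"]), samples=samples, start_s=float(meta.get("start_s", 0.0)))
    return SessionData(units=units, epochs=epochs, lfp=lfp, events=events, manifest=manifest)


def write_events(path, events: EventSeries) -> None:
    with open(path, "w") as f:
        f.write("start_s\tpeak_s\tend_s\n")
        for s, p, e in zip(events.start_s, events.peak_s, events.end_s):
            f.write(f"{s:.6f}\t{p:.6f}\t{e:.6f}\n")


def write_epochs(path, epoch_sets: list[EpochSet]) -> None:
    with open(path, "w") as f:
        f.write("label\tstart_s\tend_s\n")
        for ep in epoch_sets:
            for s, e in ep.intervals:
                f.write(f"{ep.label}\t{s:.6f}\t{e:.6f}\n")


def _gaussian_bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Zero-phase Gaussian band-pass as a difference of Gaussian low-passes.

    The Gaussian s.d. for each cutoff is chosen so the filter's amplitude
    response is 1/2 at the cutoff frequency.
    """
    c = np.sqrt(2.0 * np.log(2.0)) / (2.0 * np.pi)
    sigma_high = c / high_hz * fs  # in samples
    sigma_low = c / low_hz * fs
    return gaussian_filter1d(x, sigma_high, mode="reflect") - gaussian_filter1d(x, sigma_low, mode="reflect")


def detect_swr(
    lfp: LfpTrace,
    low_sd: float = 3.0,
    high_sd: float = 7.0,
    min_dur: float = 0.025,
    max_dur: float = 0.350,
    merge_gap: float = 0.030,
    band_hz: tuple[float, float] = (80.0, 300.0),
    smooth_window: int = 11,
    restrict: EpochSet | None = None,
) -> EventSeries:
    """Detect sharp wave-ripples on one LFP channel.

    Pipeline: Gaussian band-pass (80-300 Hz) -> square -> 11-sample moving
    average -> z-score -> candidate epochs above `low_sd` whose maximum
    exceeds `high_sd` -> duration filter [min_dur, max_dur] -> merge events
    separated by less than `merge_gap` (merged extent spans both, peak at
    the global maximum of normalized power).

    If `restrict` is given (typically NREM epochs), the z-scoring statistics
    are computed from those samples only and detections outside are dropped.
    """
    if lfp.fs_hz < 1250:
        raise ValueError("detect_swr requires fs >= 1250 Hz")
    bp = _gaussian_bandpass(lfp.samples, lfp.fs_hz, *band_hz)
    power = uniform_filter1d(bp**2, size=smooth_window, mode="reflect")
    if restrict is not None and len(restrict):
        sel = restrict.contains(lfp.times)
        mu, sd = float(power[sel].mean()), float(power[sel].std())
    else:
        mu, sd = float(power.mean()), float(power.std())
    if sd == 0:
        raise ValueError("cannot z-score: LFP band power has zero variance")
    z = (power - mu) / sd

    above = z > low_sd
    if not above.any():
        return EventSeries("swr", [], [], [])
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    cands = []
    for i0, i1 in zip(starts, ends):
        if np.max(z[i0:i1]) < high_sd:
            continue
        dur = (i1 - i0) / lfp.fs_hz
        if not (min_dur <= dur <= max_dur):
            continue
        cands.append([i0, i1])
    # merge events closer than merge_gap into unitary events
    merged = []
    for i0, i1 in cands:
        if merged and (i0 - merged[-1][1]) / lfp.fs_hz < merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    t = lfp.times
    rows = []
    for i0, i1 in merged:
        ipk = i0 + int(np.argmax(z[i0:i1]))
        rows.append((t[i0], t[ipk], t[i1 - 1]))
    if restrict is not None and len(restrict) and rows:
        rows = [r for r in rows if restrict.contains([r[1]])[0]]
    if not rows:
        return EventSeries("swr", [], [], [])
    s, p, e = map(np.array, zip(*rows))
    return EventSeries("swr", s, p, e)


def detect_up_down(
    units: list[SpikeTrain],
    nrem: EpochSet,
    bin_s: float = 0.010,
    smooth_sd: float = 0.020,
    frac: float = 0.20,
    min_down: float = 0.030,
    max_down: float = 0.500,
) -> tuple[EpochSet, EpochSet]:
    """Detect DOWN (population silence) and UP states within NREM epochs.

    Total population rate in `bin_s` bins is Gaussian-smoothed
    (`smooth_sd`); maximal runs below `frac` of the epoch's maximum smoothed
    rate, lasting [min_down, max_down], are DOWN states. UP states are the
    epochs between consecutive DOWN states.
    """
    if not len(nrem):
        raise ValueError("empty NREM epochs")
    all_spikes = np.sort(np.concatenate([u.times for u in units])) if units else np.array([])
    if all_spikes.size == 0:
        raise ValueError("need at least one unit with spikes in NREM")
    downs, ups = [], []
    for s0, e0 in nrem.intervals:
        edges = np.arange(s0, e0 + bin_s, bin_s)
        if edges.size < 3:
            continue
        counts, _ = np.histogram(all_spikes, bins=edges)
        rate = gaussian_filter1d(counts / bin_s, smooth_sd / bin_s, mode="nearest")
        thresh = frac * float(rate.max())
        below = rate < thresh
        d = np.diff(below.astype(np.int8))
        i_starts = np.flatnonzero(d == 1) + 1
        i_ends = np.flatnonzero(d == -1) + 1
        if below.size and below[0]:
            i_starts = np.r_[0, i_starts]
        if below.size and below[-1]:
            i_ends = np.r_[i_ends, below.size]
        epoch_downs = []
        for i0, i1 in zip(i_starts, i_ends):
            t0, t1 = edges[i0], edges[i1]
            if min_down <= (t1 - t0) <= max_down:
                epoch_downs.append((t0, min(t1, e0)))
        downs.extend(epoch_downs)
        for (a0, a1), (b0, b1) in zip(epoch_downs, epoch_downs[1:]):
            if b0 > a1:
                ups.append((a1, b0))
    return (
        EpochSet("up", np.array(ups, float).reshape(-1, 2)),
        EpochSet("down", np.array(downs, float).reshape(-1, 2)),
    )


def epoch_normalized_event_rate(
    events: EventSeries,
    up_epochs: EpochSet,
    down_epochs: EpochSet,
    n_norm_bins: int = 20,
):
    """Event rate over normalized DOWN+UP time.

    Each DOWN epoch and the immediately following UP epoch are rescaled to
    `n_norm_bins` bins each; the event rate (Hz) is averaged across cycles.
    Returns (bin_centers in [0, 2] normalized units with DOWN on [0, 1],
    rate per bin).
    """
    if not len(up_epochs) or not len(down_epochs):
        raise ValueError("need non-empty UP and DOWN epochs")
    peaks = events.peak_s
    nb = int(n_norm_bins)
    counts = np.zeros(2 * nb)
    occupancy = np.zeros(2 * nb)  # seconds represented by each bin
    up_starts = up_epochs.starts
    for d0, d1 in down_epochs.intervals:
        j = np.searchsorted(up_starts, d1 - 1e-9)
        if j >= len(up_epochs):
            continue
        u0, u1 = up_epochs.intervals[j]
        if u0 - d1 > 1e-6:  # not the adjacent UP
            continue
        for (a, b), off in (((d0, d1), 0), ((u0, u1), nb)):
            sel = peaks[(peaks >= a) & (peaks < b)]
            idx = off + np.minimum((((sel - a) / (b - a)) * nb).astype(int), nb - 1)
            np.add.at(counts, idx, 1.0)
            occupancy[off : off + nb] += (b - a) / nb
    rate = np.divide(counts, occupancy, out=np.zeros_like(counts), where=occupancy > 0)
    centers = (np.arange(2 * nb) + 0.5) / nb
    return centers, rate


def event_up_onset_ccg(events: EventSeries, up_epochs: EpochSet, bin_s: float = 0.025, half_window: float = 1.0):
    """Plain cross-correlogram of event peaks around UP-state onsets (no
    duration normalization)."""
    onsets = up_epochs.starts
    edges = np.arange(-half_window, half_window + bin_s, bin_s)
    counts = np.zeros(edges.size - 1)
    for t0 in onsets:
        counts += np.histogram(events.peak_s - t0, bins=edges)[0]
    rate = counts / (max(onsets.size, 1) * bin_s)
    return (edges[:-1] + edges[1:]) / 2.0, rate


def sample_baseline_events(
    nrem: EpochSet,
    n: int,
    exclusion: EventSeries | None = None,
    margin_s: float = 0.5,
    seed: int = 0,
) -> EventSeries:
    """Draw `n` baseline times uniformly over NREM minus (exclusion +/-
    margin_s); reproducible given `seed`."""
    allowed = [list(iv) for iv in nrem.intervals]
    if exclusion is not None and len(exclusion):
        for pk in exclusion.peak_s:
            lo, hi = pk - margin_s, pk + margin_s
            nxt = []
            for s, e in allowed:
                if hi <= s or lo >= e:
                    nxt.append([s, e])
                    continue
                if lo > s:
                    nxt.append([s, lo])
                if hi < e:
                    nxt.append([hi, e])
            allowed = nxt
    allowed = [(s, e) for s, e in allowed if e > s]
    total = sum(e - s for s, e in allowed)
    if total <= 0:
        raise ValueError("no NREM time left after exclusion; achievable maximum is 0 events")
    rng = stream(seed, "baseline-events")
    durs = np.array([e - s for s, e in allowed])
    starts = np.array([s for s, _ in allowed])
    pick = rng.choice(durs.size, size=n, p=durs / total)
    times = np.sort(starts[pick] + rng.uniform(0, durs[pick]))
    return EventSeries.from_peaks("baseline", times)
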