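"""ISOMAP embedding of HD population vectors and polar readout around SWRs.

The population rate matrix (square-rooted, Gaussian-smoothed counts) from
wakefulness and from windows around events is embedded jointly in 2D with
ISOMAP; each time point is then expressed in polar coordinates relative to
the center (mean) of the wake cloud, and event-locked radius / angular
velocity are normalized against baseline events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.manifold import Isomap

from .circular import circ_diff
from .core import EpochSet, SpikeTrain

__all__ = [
    "BinnedRates",
    "Embedding2D",
    "bin_transform_rates",
    "event_rate_windows",
    "isomap_embed",
    "polar_swr_stats",
    "embed_event_batches",
]


@dataclass
class BinnedRates:
    bin_centers_s: np.ndarray
    matrix: np.ndarray  # (T, N), >= 0
    sqrt_applied: bool
    smooth_sd_bins: float
    segment_ids: np.ndarray  # contiguous-window index per row


@dataclass
class Embedding2D:
    points: np.ndarray  # (T, 2)
    center: np.ndarray  # 2-vector (mean of wake points)
    radius: np.ndarray
    angle: np.ndarray
    labels: np.ndarray  # string label per row: "wake" | "swr#k" | "baseline#k"


def _bin_counts(units: list[SpikeTrain], starts: np.ndarray, bin_s: float) -> np.ndarray:
    cols = [
        (np.searchsorted(u.times, starts + bin_s) - np.searchsorted(u.times, starts)).astype(float)
        for u in units
    ]
    return np.column_stack(cols)


def bin_transform_rates(
    units: list[SpikeTrain],
    windows,
    bin_s: float,
    overlap: float = 0.5,
    apply_sqrt: bool = True,
    smooth_sd_bins: float = 3.0,
) -> BinnedRates:
    """Overlapping-bin rates -> square root -> Gaussian smoothing (sd in
    bins) along time, independently within each contiguous window."""
    step = bin_s * (1.0 - overlap)
    centers_all, rows_all, seg_all = [], [], []
    for k, (s, e) in enumerate(windows):
        starts = np.arange(s, e - bin_s + 1e-12, step)
        if starts.size == 0:
            raise ValueError(f"window ({s}, {e}) shorter than one bin")
        rates = _bin_counts(units, starts, bin_s) / bin_s
        if apply_sqrt:
            rates = np.sqrt(rates)
        if smooth_sd_bins > 0:
            rates = gaussian_filter1d(rates, smooth_sd_bins, axis=0, mode="nearest")
        centers_all.append(starts + bin_s / 2.0)
        rows_all.append(rates)
        seg_all.append(np.full(starts.size, k))
    return BinnedRates(
        bin_centers_s=np.concatenate(centers_all),
        matrix=np.vstack(rows_all),
        sqrt_applied=apply_sqrt,
        smooth_sd_bins=smooth_sd_bins,
        segment_ids=np.concatenate(seg_all),
    )


def event_rate_windows(
    units: list[SpikeTrain],
    peaks,
    half_window: float = 0.5,
    bin_s: float = 0.030,
    overlap: float = 0.5,
    apply_sqrt: bool = True,
    smooth_sd_bins: float = 3.0,
):
    """Per-event rate windows around peaks; returns (lag_centers, list of
    (L, N) matrices, one per event)."""
    step = bin_s * (1.0 - overlap)
    rel = np.arange(-half_window, half_window - bin_s + 1e-12, step)
    lags = rel + bin_s / 2.0
    mats = []
    for pk in np.asarray(peaks, float):
        rates = _bin_counts(units, pk + rel, bin_s) / bin_s
        if apply_sqrt:
            rates = np.sqrt(rates)
        if smooth_sd_bins > 0:
            rates = gaussian_filter1d(rates, smooth_sd_bins, axis=0, mode="nearest")
        mats.append(rates)
    return lags, mats


def isomap_embed(wake_rows: np.ndarray, event_rows: list[np.ndarray] | None = None,
                 event_labels: list[str] | None = None, n_neighbors: int = 200) -> Embedding2D:
    """Joint 2D ISOMAP embedding of wake rows and event-locked rows.

    The polar center is the mean of the wake points. Raises if the k-NN
    graph is disconnected.
    """
    wake_rows = np.asarray(wake_rows, float)
    if wake_rows.shape[0] <= n_neighbors:
        raise ValueError("need more wake rows than n_neighbors")
    blocks = [wake_rows]
    labels = [np.full(wake_rows.shape[0], "wake", dtype=object)]
    if event_rows:
        if event_labels is None:
            event_labels = [f"event#{k}" for k in range(len(event_rows))]
        for lbl, rows in zip(event_labels, event_rows):
            blocks.append(np.asarray(rows, float))
            labels.append(np.full(rows.shape[0], lbl, dtype=object))
    data = np.vstack(blocks)
    iso = Isomap(n_neighbors=n_neighbors, n_components=2, eigen_solver="auto")
    try:
        pts = iso.fit_transform(data)
    except Exception as err:  # disconnected graph manifests as an error here
        raise ValueError(
            f"ISOMAP embedding failed (possibly disconnected k-NN graph; try a larger n_neighbors): {err}"
        ) from err
    n_conn = getattr(iso, "nbrs_", None)
    if not np.all(np.isfinite(pts)):
        raise ValueError("disconnected k-NN graph: increase n_neighbors")
    center = pts[: wake_rows.shape[0]].mean(axis=0)
    rel = pts - center
    return Embedding2D(
        points=pts,
        center=center,
        radius=np.linalg.norm(rel, axis=1),
        angle=np.arctan2(rel[:, 1], rel[:, 0]),
        labels=np.concatenate(labels),
    )


def embed_event_batches(
    wake_rows: np.ndarray,
    swr_mats: list[np.ndarray],
    baseline_mats: list[np.ndarray],
    n_neighbors: int = 200,
    batch_size: int = 150,
):
    """Embed SWR and baseline windows in batches against a fixed wake block.

    Each batch holds `batch_size` SWR windows and the same number of
    baseline windows; batches are repeated until all SWRs are processed.
    Returns (radius_swr, angle_swr, radius_base, angle_base), each an
    (n_events, n_lags) array pooled across batches.
    """
    if len(swr_mats) == 0:
        raise ValueError("no events")
    n_lags = swr_mats[0].shape[0]
    r_swr, a_swr, r_base, a_base = [], [], [], []
    n_batches = int(np.ceil(len(swr_mats) / batch_size))
    for b in range(n_batches):
        swr_batch = swr_mats[b * batch_size : (b + 1) * batch_size]
        base_idx = [(b * batch_size + j) % len(baseline_mats) for j in range(len(swr_batch))]
        base_batch = [baseline_mats[j] for j in base_idx]
        rows = swr_batch + base_batch
        labels = [f"swr#{b * batch_size + j}" for j in range(len(swr_batch))] + [
            f"baseline#{j}" for j in base_idx
        ]
        emb = isomap_embed(wake_rows, rows, labels, n_neighbors=n_neighbors)
        off = wake_rows.shape[0]
        for k in range(len(swr_batch)):
            sl = slice(off + k * n_lags, off + (k + 1) * n_lags)
            r_swr.append(emb.radius[sl])
            a_swr.append(emb.angle[sl])
        off2 = off + len(swr_batch) * n_lags
        for k in range(len(base_batch)):
            sl = slice(off2 + k * n_lags, off2 + (k + 1) * n_lags)
            r_base.append(emb.radius[sl])
            a_base.append(emb.angle[sl])
    return np.vstack(r_swr), np.vstack(a_swr), np.vstack(r_base), np.vstack(a_base)


def polar_swr_stats(
    radius_swr: np.ndarray,
    angle_swr: np.ndarray,
    radius_base: np.ndarray,
    angle_base: np.ndarray,
    lags: np.ndarray,
    event_mask: np.ndarray | None = None,
):
    """Normalized radius and angular velocity around events.

    Both statistics are expressed as (X_events - X_baseline) / X_baseline
    with the baseline mean taken per lag (this cancels lag-structure shared
    by both event sets, e.g. smoothing edge effects of the short windows).
    Returns a dict with per-lag profiles and the radius argmax / velocity
    argmin lags. `event_mask` optionally restricts which events enter (e.g.
    to exclude SWRs shortly after UP onset).
    """
    lags = np.asarray(lags, float)
    if event_mask is not None:
        radius_swr = radius_swr[event_mask]
        angle_swr = angle_swr[event_mask]
    if radius_swr.shape[0] == 0:
        raise ValueError("no events after masking")
    r_base = radius_base.mean(axis=0)
    norm_radius = (radius_swr.mean(axis=0) - r_base) / r_base

    v_swr = np.abs(circ_diff(angle_swr[:, 1:], angle_swr[:, :-1]))
    v_bl = np.abs(circ_diff(angle_base[:, 1:], angle_base[:, :-1]))
    v_base = v_bl.mean(axis=0)
    norm_velocity = (v_swr.mean(axis=0) - v_base) / v_base
    lag_mids = (lags[1:] + lags[:-1]) / 2.0
    return {
        "lags": lags,
        "norm_radius": norm_radius,
        "radius_peak_lag": float(lags[np.argmax(norm_radius)]),
        "velocity_lags": lag_mids,
        "norm_velocity": norm_velocity,
        "velocity_min_lag": float(lag_mids[np.argmin(norm_velocity)]),
    }
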