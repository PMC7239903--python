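"""HD tuning curves, Rayleigh classification and Bayesian angle decoding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .circular import circ_diff, kappa_from_resultant, rayleigh_test, resultant_length, wrap
from .core import EpochSet, SpikeTrain

__all__ = [
    "TuningCurve",
    "DecodedSeries",
    "compute_tuning_curve",
    "classify_hd",
    "bayesian_decode",
    "decode_around_events",
    "angular_velocity_ratio",
]


@dataclass
class TuningCurve:
    bin_centers: np.ndarray  # radians, uniform over [0, 2pi)
    rates: np.ndarray  # Hz; NaN where occupancy is zero
    occupancy: np.ndarray  # seconds per bin
    peak_rate: float
    rayleigh_p: float
    kappa: float

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def preferred_direction(self) -> float:
        return float(self.bin_centers[np.nanargmax(self.rates)])


@dataclass
class DecodedSeries:
    bin_centers_s: np.ndarray
    angle: np.ndarray  # decoded direction, radians
    posterior_max: np.ndarray
    counts: np.ndarray  # (T, N) spike counts per bin
    posterior: np.ndarray | None = None  # (T, A), rows sum to 1


def _interp_angle(hd_times: np.ndarray, hd_angles: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Interpolate a wrapped angular signal at arbitrary times."""
    unwrapped = np.unwrap(hd_angles)
    return wrap(np.interp(at, hd_times, unwrapped))


def compute_tuning_curve(
    spikes: SpikeTrain,
    hd_times,
    hd_angles,
    n_bins: int = 60,
    epoch: EpochSet | None = None,
    smooth_sd_bins: float = 0.0,
) -> TuningCurve:
    """Tuning curve = spike count per angular bin / occupancy time per bin.

    Bins with zero occupancy are NaN (undefined), not zero. The Rayleigh
    test runs on per-spike headings weighted by inverse occupancy; kappa is
    estimated from the resultant length of the occupancy-normalized curve.
    `smooth_sd_bins` > 0 applies circular Gaussian smoothing to the rates
    (only when every bin is defined).
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    hd_times = np.asarray(hd_times, float)
    hd_angles = np.asarray(hd_angles, float)
    if epoch is not None:
        sel = epoch.contains(hd_times)
        if not sel.any():
            raise ValueError("epoch contains no HD samples")
        spk = spikes.restrict(epoch)
    else:
        sel = np.ones(hd_times.shape, bool)
        spk = spikes.times
    dt = float(np.median(np.diff(hd_times)))
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0

    occ_counts, _ = np.histogram(wrap(hd_angles[sel]), bins=edges)
    occupancy = occ_counts * dt

    spk = spk[(spk >= hd_times[0]) & (spk <= hd_times[-1])]
    spike_angles = _interp_angle(hd_times, hd_angles, spk)
    spike_counts, _ = np.histogram(spike_angles, bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occupancy > 0, spike_counts / np.where(occupancy > 0, occupancy, 1.0), np.nan)
    peak_rate = float(np.nanmax(rates)) if np.isfinite(rates).any() else 0.0
    if spike_counts.sum() == 0:
        rates = np.where(occupancy > 0, 0.0, np.nan)
        peak_rate = 0.0
    if smooth_sd_bins > 0 and np.all(np.isfinite(rates)):
        from scipy.ndimage import gaussian_filter1d

        rates = gaussian_filter1d(rates, smooth_sd_bins, mode="wrap")
        peak_rate = float(rates.max())

    if spk.size >= 2:
        bin_idx = np.minimum((spike_angles / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
        occ_w = occupancy[bin_idx]
        weights = np.where(occ_w > 0, 1.0 / np.where(occ_w > 0, occ_w, 1.0), 0.0)
        if weights.sum() > 0:
            _, p = rayleigh_test(spike_angles, weights)
        else:
            p = 1.0
    else:
        p = 1.0

    w = np.where(np.isfinite(rates), rates, 0.0)
    kappa = kappa_from_resultant(resultant_length(centers, w)) if w.sum() > 0 else 0.0
    return TuningCurve(
        bin_centers=centers,
        rates=rates,
        occupancy=occupancy,
        peak_rate=peak_rate,
        rayleigh_p=float(p),
        kappa=float(kappa),
    )


def classify_hd(tuning: TuningCurve) -> bool:
    """HD iff peak rate > 1 Hz, Rayleigh p < 0.001 and kappa > 1."""
    return bool(tuning.peak_rate > 1.0 and tuning.rayleigh_p < 1e-3 and tuning.kappa > 1.0)


def _rate_matrix(tunings: list[TuningCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = tunings[0].bin_centers
    for tc in tunings[1:]:
        if tc.n_bins != centers.size:
            raise ValueError("all tuning curves must share the same angular binning")
    f = np.vstack([tc.rates for tc in tunings])  # (N, A)
    angle_ok = np.all(np.isfinite(f), axis=0)
    if not angle_ok.any():
        raise ValueError("no angular bin has defined tuning for every unit")
    return f, centers, angle_ok


def _decode_counts(counts: np.ndarray, f: np.ndarray, centers: np.ndarray, angle_ok: np.ndarray, tau: float):
    """Log-domain Poisson decoding of a (T, N) count matrix."""
    fa = f[:, angle_ok]  # (N, A')
    with np.errstate(divide="ignore"):
        logf = np.where(fa > 0, np.log(tau * np.where(fa > 0, fa, 1.0)), -1e12)
    loglik = counts @ logf - tau * fa.sum(axis=0)  # (T, A')
    norm = logsumexp(loglik, axis=1, keepdims=True)
    post = np.exp(loglik - norm)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmax(post, axis=1)
    valid_centers = centers[angle_ok]
    full_post = np.zeros((counts.shape[0], centers.size))
    full_post[:, angle_ok] = post
    return valid_centers[idx], post[np.arange(idx.size), idx], full_post


def _count_in_bins(times: np.ndarray, starts: np.ndarray, bin_s: float) -> np.ndarray:
    return (np.searchsorted(times, starts + bin_s) - np.searchsorted(times, starts)).astype(float)


def bayesian_decode(
    units: list[SpikeTrain],
    tunings: list[TuningCurve],
    epoch: EpochSet,
    bin_s: float = 0.030,
    overlap: float = 0.5,
    keep_posterior: bool = False,
) -> DecodedSeries:
    """Decode direction from population spike counts with a flat prior.

    Per time bin the posterior over angle bins is proportional to
    prod_i (tau f_i)^n_i exp(-tau f_i), evaluated in the log domain; the
    decoded angle is the posterior argmax. Bins start every
    bin_s * (1 - overlap) within each interval of `epoch`.
    """
    f, centers, angle_ok = _rate_matrix(tunings)
    step = bin_s * (1.0 - overlap)
    starts_all, counts_all = [], []
    for s, e in epoch.intervals:
        starts = np.arange(s, e - bin_s + 1e-12, step)
        if starts.size == 0:
            continue
        counts = np.column_stack([_count_in_bins(u.times, starts, bin_s) for u in units])
        starts_all.append(starts)
        counts_all.append(counts)
    if not starts_all:
        raise ValueError("epoch too short for the requested bin size")
    starts = np.concatenate(starts_all)
    counts = np.vstack(counts_all)
    angle, pmax, post = _decode_counts(counts, f, centers, angle_ok, bin_s)
    return DecodedSeries(
        bin_centers_s=starts + bin_s / 2.0,
        angle=angle,
        posterior_max=pmax,
        counts=counts,
        posterior=post if keep_posterior else None,
    )


def decode_around_events(
    units: list[SpikeTrain],
    tunings: list[TuningCurve],
    event_peaks,
    half_window: float = 0.5,
    bin_s: float = 0.030,
    overlap: float = 0.5,
):
    """Decode in lag bins around each event peak.

    Returns (lag_centers, angles) where angles has shape (n_events, n_lags).
    """
    f, centers, angle_ok = _rate_matrix(tunings)
    peaks = np.asarray(event_peaks, float)
    step = bin_s * (1.0 - overlap)
    rel_starts = np.arange(-half_window, half_window - bin_s + 1e-12, step)
    lags = rel_starts + bin_s / 2.0
    angles = np.empty((peaks.size, rel_starts.size))
    for k, pk in enumerate(peaks):
        starts = pk + rel_starts
        counts = np.column_stack([_count_in_bins(u.times, starts, bin_s) for u in units])
        angles[k], _, _ = _decode_counts(counts, f, centers, angle_ok, bin_s)
    return lags, angles


def angular_velocity_ratio(angles_events: np.ndarray, angles_baseline: np.ndarray, lags: np.ndarray):
    """Normalized angular velocity time course around events.

    Velocity is the absolute circular difference between consecutive decoded
    angles, averaged across events per lag; the ratio is
    (v_events(lag) - v_baseline) / v_baseline with v_baseline the grand mean
    over baseline events and lags. Returns (lag_mids, ratio, lag_of_min).
    """
    if angles_events.shape[0] < 10:
        warnings.warn("fewer than 10 events: velocity ratio is unstable", RuntimeWarning)
    v_ev = np.abs(circ_diff(angles_events[:, 1:], angles_events[:, :-1]))
    v_bl = np.abs(circ_diff(angles_baseline[:, 1:], angles_baseline[:, :-1]))
    v_lag = v_ev.mean(axis=0)
    v_base = float(v_bl.mean())
    if v_base == 0:
        ratio = np.where(v_lag == 0, -1.0, np.inf)
    else:
        ratio = (v_lag - v_base) / v_base
    mids = (np.asarray(lags)[1:] + np.asarray(lags)[:-1]) / 2.0
    return mids, ratio, float(mids[np.argmin(ratio)])
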