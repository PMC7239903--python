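"""Event-triggered cross-correlograms with slow-comodulation-corrected
z-normalization, SWR energy, theta phase modulation, and jPCA phases.

The z-normalization follows a null model of no fast coupling: the observed
CCG is low-passed (Gaussian, 150 ms s.d.) to obtain an expected rate; the
expected count per bin and its Poisson standard deviation then convert the
observed counts into deviations z(t). These z values are not a classical
z-score — their mean and s.d. are not normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .circular import circ_mean, circular_correlation, rayleigh_test, resultant_length
from .core import EpochSet, EventSeries, LfpTrace, SpikeTrain

__all__ = [
    "Correlogram",
    "ThetaModulation",
    "JpcaModel",
    "event_cross_correlogram",
    "z_normalize_ccg",
    "swr_energy",
    "theta_phases",
    "assign_spike_phases",
    "theta_modulation",
    "fit_antisymmetric_dynamics",
    "jpca_fit",
    "swr_phase",
    "circular_correlation",
]


@dataclass
class Correlogram:
    lag_centers_s: np.ndarray
    rate: np.ndarray  # Hz per lag
    n_ref: int
    bin_s: float
    counts: np.ndarray | None = None
    z: np.ndarray | None = None  # normalized values; NaN where expected count is 0
    expected_rate: np.ndarray | None = None


@dataclass
class ThetaModulation:
    preferred_phase: float
    depth: float  # mean resultant length, in [0, 1]
    rayleigh_p: float
    n_spikes: int
    reliable: bool = True


def event_cross_correlogram(
    spikes: SpikeTrain | np.ndarray,
    events: EventSeries | np.ndarray,
    bin_s: float = 0.005,
    half_window: float = 0.5,
) -> Correlogram:
    """Average firing rate in lag bins relative to event peak times.

    rate(lag) = count(lag) / (n_events * bin_s).
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    peaks = events.peak_s if isinstance(events, EventSeries) else np.asarray(events, float)
    if peaks.size < 1:
        raise ValueError("no events")
    n_bins = int(round(2 * half_window / bin_s))
    edges = -half_window + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for pk in peaks:
        lo = np.searchsorted(times, pk - half_window)
        hi = np.searchsorted(times, pk + half_window)
        if hi > lo:
            counts += np.histogram(times[lo:hi] - pk, bins=edges)[0]
    rate = counts / (peaks.size * bin_s)
    return Correlogram(
        lag_centers_s=(edges[:-1] + edges[1:]) / 2.0,
        rate=rate,
        n_ref=int(peaks.size),
        bin_s=bin_s,
        counts=counts,
    )


def z_normalize_ccg(ccg: Correlogram, smooth_sd: float = 0.150) -> Correlogram:
    """Normalize a CCG against its own slow (low-passed) component.

    Expected rate = CCG convolved with a Gaussian of `smooth_sd`; the
    expected count is mu = expected_rate * n_ref * bin, and
    z = (count - mu) / sqrt(mu), with edges handled by reflection. Bins
    where mu = 0 are masked (NaN).
    """
    counts = ccg.counts if ccg.counts is not None else ccg.rate * ccg.n_ref * ccg.bin_s
    expected_rate = gaussian_filter1d(ccg.rate, smooth_sd / ccg.bin_s, mode="reflect")
    mu = expected_rate * ccg.n_ref * ccg.bin_s
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mu > 0, (counts - mu) / np.sqrt(np.where(mu > 0, mu, 1.0)), np.nan)
    return Correlogram(
        lag_centers_s=ccg.lag_centers_s,
        rate=ccg.rate,
        n_ref=ccg.n_ref,
        bin_s=ccg.bin_s,
        counts=counts,
        z=z,
        expected_rate=expected_rate,
    )


def swr_energy(z: np.ndarray, variant: str = "power") -> float:
    """SWR energy of a z-normalized CCG.

    "power" (default): Euclidean norm sqrt(sum z^2) over defined lag bins.
    "variance": the variance of the z values (alternative definition).
    """
    z = np.asarray(z, float)
    z = z[np.isfinite(z)]
    if variant == "power":
        return float(np.sqrt(np.sum(z**2)))
    if variant == "variance":
        return float(np.var(z))
    raise ValueError("variant must be 'power' or 'variance'")


# ----------------------------------------------------------------------------
# theta phase


@dataclass
class PhaseSeries:
    times: np.ndarray
    phase: np.ndarray  # radians in [0, 2pi); NaN outside epochs


def _morlet_kernel(freq: float, fs: float, w: float = 6.0) -> np.ndarray:
    sd_t = w / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sd_t**2))


def theta_phases(
    lfp: LfpTrace,
    epochs: EpochSet,
    band_hz: tuple[float, float] = (5.0, 12.0),
    n_freqs: int = 8,
    wavelet_w: float = 6.0,
) -> PhaseSeries:
    """Instantaneous theta phase from a Morlet wavelet ridge.

    For each sample inside `epochs` the phase of the maximal-power scale
    within `band_hz` is taken. Epochs shorter than two cycles of the lower
    band edge are skipped with a warning.
    """
    freqs = np.geomspace(band_hz[0], band_hz[1], n_freqs)
    t = lfp.times
    phase = np.full(t.size, np.nan)
    min_dur = 2.0 / band_hz[0]
    for s, e in epochs.intervals:
        if e - s < min_dur:
            warnings.warn(f"epoch ({s:.3f}, {e:.3f}) shorter than 2 theta cycles: skipped", RuntimeWarning)
            continue
        i0, i1 = lfp.sample_index(s), lfp.sample_index(e) + 1
        seg = lfp.samples[i0:i1]
        coeffs = np.empty((n_freqs, seg.size), dtype=complex)
        for k, f0 in enumerate(freqs):
            kern = _morlet_kernel(f0, lfp.fs_hz, wavelet_w)
            coeffs[k] = fftconvolve(seg, kern, mode="same")
        ridge = np.argmax(np.abs(coeffs), axis=0)
        phase[i0:i1] = np.mod(np.angle(coeffs[ridge, np.arange(seg.size)]), 2 * np.pi)
    return PhaseSeries(times=t, phase=phase)


def assign_spike_phases(spikes: SpikeTrain | np.ndarray, phases: PhaseSeries) -> np.ndarray:
    """Map each spike to the theta phase of its nearest LFP sample; spikes
    outside phase-defined epochs are dropped."""
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    dt = float(phases.times[1] - phases.times[0])
    idx = np.round((times - phases.times[0]) / dt).astype(int)
    ok = (idx >= 0) & (idx < phases.times.size)
    ph = phases.phase[idx[ok]]
    return ph[np.isfinite(ph)]


def theta_modulation(spike_phases: np.ndarray) -> ThetaModulation:
    """Preferred phase (circular mean), depth (resultant length) and
    Rayleigh p of the spike phase distribution."""
    ph = np.asarray(spike_phases, float)
    ph = ph[np.isfinite(ph)]
    if ph.size < 10:
        return ThetaModulation(np.nan, np.nan, 1.0, int(ph.size), reliable=False)
    r, p = rayleigh_test(ph)
    return ThetaModulation(circ_mean(ph), r, p, int(ph.size))


# ----------------------------------------------------------------------------
# jPCA


@dataclass
class JpcaModel:
    mean_ccg: np.ndarray  # (T,) mean over units, removed before PCA
    basis: np.ndarray  # (K, T) orthonormal PCA waveforms
    scores: np.ndarray  # (N, K) per-unit PC scores
    M: np.ndarray  # unconstrained least-squares dynamics matrix
    M_anti: np.ndarray  # antisymmetric least-squares fit
    eigvals: np.ndarray
    U: np.ndarray  # (K, 2) real jPC pair
    y: np.ndarray  # (N, 2) per-unit projections
    phases: np.ndarray  # (N,) phi = atan2(y2, y1)


def fit_antisymmetric_dynamics(X: np.ndarray, Xdot: np.ndarray) -> np.ndarray:
    """Least-squares antisymmetric M minimizing ||Xdot - X M^T||_F.

    X, Xdot: (T, K) state and derivative samples. Solved in closed form in
    the K(K-1)/2-dimensional parameterization of antisymmetric matrices.
    """
    X = np.asarray(X, float)
    Xdot = np.asarray(Xdot, float)
    T, K = X.shape
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    design = np.zeros((T * K, len(pairs)))
    for p, (i, j) in enumerate(pairs):
        contrib = np.zeros((T, K))
        contrib[:, i] = -X[:, j]  # M[i, j] = -a  => row i gets -a * x_j
        contrib[:, j] = X[:, i]  # M[j, i] = +a  => row j gets +a * x_i
        design[:, p] = contrib.ravel()
    coef, *_ = np.linalg.lstsq(design, Xdot.ravel(), rcond=None)
    M = np.zeros((K, K))
    for p, (i, j) in enumerate(pairs):
        M[i, j] = -coef[p]
        M[j, i] = coef[p]
    return M


def jpca_fit(Z: np.ndarray, K: int = 6, dt: float = 1.0, smooth_sd_bins: float = 0.0) -> JpcaModel:
    """Fit rotational (jPCA) dynamics to a units x lags matrix of z-scored
    CCGs.

    PCA (over lags) reduces the population trajectory to K dimensions; an
    antisymmetric dynamics matrix is fitted by closed-form least squares on
    forward differences; the jPC pair comes from the conjugate eigenvector
    pair with the largest imaginary eigenvalue, realified as u1 = v1 + v2,
    u2 = i(v1 - v2). Each unit's phase is atan2 of its projection onto
    (u1, u2).

    `smooth_sd_bins` > 0 low-passes each curve along lags first; with
    unsmoothed bin-level noise the derivative fit otherwise latches onto a
    fast-rotating noise plane instead of the signal plane.
    """
    Z = np.asarray(Z, float)
    if smooth_sd_bins > 0:
        Z = gaussian_filter1d(Z, smooth_sd_bins, axis=1, mode="reflect")
    N, T = Z.shape
    if T < 3:
        raise ValueError("need at least 3 lag bins")
    K = min(K, N, T)
    mean_ccg = Z.mean(axis=0)
    Zc = Z - mean_ccg
    U_svd, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if rank < K:
        warnings.warn(f"rank-deficient PCA: reducing K from {K} to {max(rank, 2)}", RuntimeWarning)
        K = max(rank, 2)
    basis = Vt[:K]  # (K, T)
    scores = U_svd[:, :K] * S[:K]  # (N, K)

    X = basis.T * S[:K]  # (T, K) population trajectory in PC space
    Xdot = np.diff(X, axis=0) / dt
    Xmid = X[:-1]
    M_full, *_ = np.linalg.lstsq(Xmid, Xdot, rcond=None)
    M_full = M_full.T
    M_anti = fit_antisymmetric_dynamics(Xmid, Xdot)

    eigvals, eigvecs = np.linalg.eig(M_anti)
    order = np.argsort(-np.abs(eigvals.imag))
    lead = order[0]
    v1 = eigvecs[:, lead]
    v2 = np.conj(v1)
    u1 = np.real(v1 + v2)
    u2 = np.real(1j * (v1 - v2))
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate rotational eigenvector pair")
    U = np.column_stack([u1 / n1, u2 / n2])  # (K, 2)
    y = scores @ U
    phases = np.arctan2(y[:, 1], y[:, 0])
    return JpcaModel(
        mean_ccg=mean_ccg,
        basis=basis,
        scores=scores,
        M=M_full,
        M_anti=M_anti,
        eigvals=eigvals,
        U=U,
        y=y,
        phases=phases,
    )


def swr_phase(z_i: np.ndarray, model: JpcaModel) -> float:
    """Phase of one CCG in the fitted jPC plane.

    Projects the (mean-removed) curve through the PCA basis onto (u1, u2);
    invariant to scaling of z_i. Raises on a zero projection.
    """
    z_i = np.asarray(z_i, float)
    w = model.basis @ (z_i - model.mean_ccg)  # (K,)
    y = w @ model.U
    if np.allclose(y, 0):
        raise ValueError("zero projection onto the jPC plane: phase undefined")
    return float(np.arctan2(y[1], y[0]))
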