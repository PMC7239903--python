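"""Auto-correlograms across brain states, burst index, intrinsic-timescale
fits, clustering of auto-correlogram shapes, and within-shank pairwise
correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .core import EpochSet, SpikeTrain

__all__ = [
    "auto_correlogram",
    "burst_index",
    "fit_decay_time",
    "stack_autocorr_features",
    "cluster_autocorrs",
    "within_shank_pairwise_correlation",
    "DecayFit",
]

BURST_ISI_LO = 0.002  # s
BURST_ISI_HI = 0.009  # s


def auto_correlogram(
    spikes: SpikeTrain | np.ndarray,
    epoch: EpochSet | None,
    bin_s: float = 0.0005,
    max_lag_s: float = 0.04,
):
    """Auto-correlogram at positive lags, normalized to rate (Hz).

    Counts pairs of spikes (i < j) with lag in (0, max_lag]; pairs spanning
    different epoch intervals are excluded. value = count / (n_spikes * bin).
    Zero lag is excluded by construction (first bin starts at 0+).
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if epoch is not None:
        segments = [times[(times >= s) & (times < e)] for s, e in epoch.intervals]
    else:
        segments = [times]
    n_bins = int(round(max_lag_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    n_spikes = 0
    for seg in segments:
        n_spikes += seg.size
        if seg.size < 2:
            continue
        m = seg.size
        hi = np.searchsorted(seg, seg + max_lag_s, side="right")
        pair_counts = hi - np.arange(m) - 1
        total = int(pair_counts.sum())
        if total == 0:
            continue
        i_idx = np.repeat(np.arange(m), pair_counts)
        offsets = np.concatenate([[0], np.cumsum(pair_counts)[:-1]])
        j_idx = np.arange(total) - np.repeat(offsets, pair_counts) + i_idx + 1
        counts += np.histogram(seg[j_idx] - seg[i_idx], bins=edges)[0]
    if n_spikes < 2:
        raise ValueError("need at least 2 spikes in the epoch")
    values = counts / (n_spikes * bin_s)
    lags = (edges[:-1] + edges[1:]) / 2.0
    return lags, values


def burst_index(spikes: SpikeTrain | np.ndarray, epoch: EpochSet) -> float:
    """Observed count of ISIs in (2, 9] ms over the count expected from a
    homogeneous Poisson process of equal mean rate:
    N_expected = T * (exp(-tau1 * r) - exp(-tau2 * r)).
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    T = epoch.total_duration()
    if T <= 0:
        raise ValueError("epoch duration must be positive")
    observed = 0
    n_spikes = 0
    for s, e in epoch.intervals:
        seg = times[(times >= s) & (times < e)]
        n_spikes += seg.size
        if seg.size >= 2:
            isi = np.diff(seg)
            observed += int(np.sum((isi > BURST_ISI_LO) & (isi <= BURST_ISI_HI)))
    r = n_spikes / T
    if r == 0:
        raise ValueError("zero firing rate: burst index undefined")
    # expected band ISI count for a homogeneous process of the same rate:
    # each of the ~rT ISIs falls in (tau1, tau2] with probability
    # exp(-tau1*r) - exp(-tau2*r), so a Poisson train scores 1.
    expected = r * T * (np.exp(-BURST_ISI_LO * r) - np.exp(-BURST_ISI_HI * r))
    return float(observed / expected)


def expected_burst_count(rate_hz: float, duration_s: float) -> float:
    """Closed-form expected 2-9 ms ISI count for a homogeneous process."""
    return duration_s * (np.exp(-BURST_ISI_LO * rate_hz) - np.exp(-BURST_ISI_HI * rate_hz))


@dataclass
class DecayFit:
    tau: float
    amplitude: float
    offset: float
    converged: bool
    reliable: bool


def fit_decay_time(lags: np.ndarray, values: np.ndarray, fit_range=(0.01, 2.5)) -> DecayFit:
    """Least-squares exponential fit A*exp(-t/tau) + B of a slow
    auto-correlogram over `fit_range` lags."""
    lags = np.asarray(lags, float)
    values = np.asarray(values, float)
    sel = (lags >= fit_range[0]) & (lags <= fit_range[1]) & np.isfinite(values)
    if sel.sum() < 20:
        raise ValueError("need at least 20 lag bins in the fit range")
    x, y = lags[sel], values[sel]
    spread = float(y.max() - y.min())
    b0 = float(y[-max(3, y.size // 10) :].mean())
    a0 = float(y[0] - b0)
    if abs(a0) < 1e-12:
        a0 = max(spread, 1e-6)
    tau0 = max((x[-1] - x[0]) / 4.0, x[0])
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau, b: a * np.exp(-t / tau) + b,
            x,
            y,
            p0=(a0, tau0, b0),
            maxfev=10000,
            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 100.0, np.inf]),
        )
        a, tau, b = map(float, popt)
        converged = True
    except RuntimeError:
        return DecayFit(np.nan, np.nan, np.nan, converged=False, reliable=False)
    scale = max(abs(b), spread, 1e-12)
    reliable = abs(a) > 0.02 * scale and 1e-4 < tau < 99.0
    return DecayFit(tau=tau, amplitude=a, offset=b, converged=converged, reliable=reliable)


def stack_autocorr_features(
    units: list[SpikeTrain],
    epochs: dict[str, EpochSet],
    bin_s: float = 0.0005,
    feat_range=(0.002, 0.040),
    norm_range=(0.050, 0.100),
    state_order=("wake", "rem", "nrem"),
) -> np.ndarray:
    """Stacked per-state auto-correlogram feature vectors.

    For each unit and brain state the 2-40 ms lags of the auto-correlogram
    are divided by the unit's mean value over the 50-100 ms lags of the same
    state (removing rate dependence) and concatenated.
    """
    feats = []
    for u in units:
        per_state = []
        for st in state_order:
            lags, vals = auto_correlogram(u, epochs[st], bin_s=bin_s, max_lag_s=norm_range[1])
            base = vals[(lags >= norm_range[0]) & (lags <= norm_range[1])].mean()
            sel = (lags >= feat_range[0]) & (lags <= feat_range[1])
            per_state.append(vals[sel] / base if base > 0 else vals[sel])
        feats.append(np.concatenate(per_state))
    return np.vstack(feats)


def cluster_autocorrs(
    X: np.ndarray,
    k: int = 2,
    hd_labels: np.ndarray | None = None,
    tsne_seed: int = 0,
    n_init: int = 50,
    with_tsne: bool = True,
):
    """K-means (k=2 by default) on stacked auto-correlogram vectors, plus an
    optional t-SNE map for inspection only.

    If `hd_labels` is given, clusters are relabeled so cluster 1 is the one
    with the higher fraction of HD units. Returns (cluster_ids starting at
    1, tsne_xy or None).
    """
    X = np.asarray(X, float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=tsne_seed)
    ids = km.fit_predict(X)
    if hd_labels is not None:
        hd = np.asarray(hd_labels, bool)
        fracs = [hd[ids == c].mean() if np.any(ids == c) else 0.0 for c in range(k)]
        order = np.argsort(fracs)[::-1]  # cluster with most HD first
        remap = np.empty(k, int)
        remap[order] = np.arange(k)
        ids = remap[ids]
    xy = None
    if with_tsne:
        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        xy = TSNE(n_components=2, perplexity=perplexity, random_state=tsne_seed, init="pca").fit_transform(X)
    return ids + 1, xy


def within_shank_pairwise_correlation(
    curves: np.ndarray,
    shank_ids,
    hd_labels,
):
    """Pearson r between curves of same-shank unit pairs, split into HD-HD
    pairs versus all other pairs; reports a two-sample t statistic.

    Returns dict with 'r_hd', 'r_other', 't', 'p'.
    """
    curves = np.asarray(curves, float)
    shank_ids = np.asarray(shank_ids)
    hd = np.asarray(hd_labels, bool)
    r_hd, r_other = [], []
    for shank in np.unique(shank_ids):
        idx = np.flatnonzero(shank_ids == shank)
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                i, j = idx[a], idx[b]
                sa, sb = np.std(curves[i]), np.std(curves[j])
                if sa == 0 or sb == 0:
                    continue
                r = float(np.corrcoef(curves[i], curves[j])[0, 1])
                (r_hd if hd[i] and hd[j] else r_other).append(r)
    if r_hd and r_other:
        t, p = stats.ttest_ind(r_hd, r_other, equal_var=False)
    else:
        t, p = np.nan, np.nan
    return {"r_hd": np.array(r_hd), "r_other": np.array(r_other), "t": float(t), "p": float(p)}
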