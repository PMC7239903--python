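"""Statistics linking spike-train dynamics to SWR coupling: PCA weights,
determinant-based total correlation with shuffle nulls and partial variants,
and HD-vs-non-HD classification from auto-correlograms with a
shuffle-referenced score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .rng import stream

__all__ = [
    "PcWeights",
    "TotalCorrelation",
    "ScoreReport",
    "pca_weights",
    "total_correlation",
    "shuffle_null",
    "partial_total_correlation",
    "modulation_strength_correlation",
    "classification_score",
    "train_hd_classifier",
]


@dataclass
class PcWeights:
    weights: np.ndarray  # (units, n_components)
    explained_variance_ratio: np.ndarray
    source: str = ""


@dataclass
class TotalCorrelation:
    C: np.ndarray  # stacked correlation matrix
    rho2: float  # 1 - det(C)


@dataclass
class ScoreReport:
    score: float
    max_lag_s: float
    labels: np.ndarray
    predictions: np.ndarray
    shuffle_predictions: np.ndarray
    fold_accuracies: np.ndarray
    shuffle_accuracies: np.ndarray  # correct counts across shuffle runs


def pca_weights(curve_matrix: np.ndarray, n_components: int = 10, source: str = "") -> PcWeights:
    """Mean-centered PCA scores of a (units x features) curve matrix."""
    X = np.asarray(curve_matrix, float)
    if X.shape[0] <= n_components:
        raise ValueError("need more units than components")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank, X.shape[1])
    if k < n_components:
        warnings.warn(f"rank {rank} < {n_components}: keeping {k} components", RuntimeWarning)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PcWeights(weights=scores, explained_variance_ratio=pca.explained_variance_ratio_, source=source)


def _corr_det(C: np.ndarray) -> float:
    """Determinant via eigenvalues, clipping tiny negatives/near-zeros."""
    ev = np.linalg.eigvalsh((C + C.T) / 2.0)
    ev = np.where(ev < 1e-12, 0.0, ev)
    return float(np.prod(ev))


def _stacked_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sa, sb = A.std(axis=0), B.std(axis=0)
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("constant weight column: correlation undefined")
    return np.corrcoef(np.hstack([A, B]), rowvar=False)


def total_correlation(A: PcWeights | np.ndarray, B: PcWeights | np.ndarray) -> TotalCorrelation:
    """Total correlation rho^2 = 1 - det(C) of the stacked weight columns.

    With one component per side this reduces to the squared Pearson
    correlation between the two score vectors.
    """
    Aw = A.weights if isinstance(A, PcWeights) else np.asarray(A, float)
    Bw = B.weights if isinstance(B, PcWeights) else np.asarray(B, float)
    if Aw.shape[0] != Bw.shape[0]:
        raise ValueError("A and B must describe the same units")
    C = _stacked_corr(Aw, Bw)
    rho2 = float(np.clip(1.0 - _corr_det(C), 0.0, 1.0))
    return TotalCorrelation(C=C, rho2=rho2)


def shuffle_null(
    A: PcWeights | np.ndarray,
    B: PcWeights | np.ndarray,
    mode: str = "global",
    n: int = 1000,
    seed: int = 0,
    shank_ids=None,
):
    """Null distribution of rho^2 from row-permutations of B.

    mode "global": unrestricted permutation; "within_shank": rows permuted
    only within groups sharing a shank id. p = (1 + #null >= observed) /
    (1 + n).
    """
    Aw = A.weights if isinstance(A, PcWeights) else np.asarray(A, float)
    Bw = B.weights if isinstance(B, PcWeights) else np.asarray(B, float)
    obs = total_correlation(Aw, Bw).rho2
    rng = stream(seed, f"shuffle-{mode}")
    n_units = Aw.shape[0]
    if mode == "within_shank":
        if shank_ids is None:
            raise ValueError("within_shank mode requires shank_ids")
        shank_ids = np.asarray(shank_ids)
        groups = [np.flatnonzero(shank_ids == s) for s in np.unique(shank_ids)]
        if all(g.size < 2 for g in groups):
            raise ValueError("within_shank shuffle degenerate: all shank groups have a single unit")
    elif mode != "global":
        raise ValueError("mode must be 'global' or 'within_shank'")
    null = np.empty(n)
    for it in range(n):
        if mode == "global":
            perm = rng.permutation(n_units)
        else:
            perm = np.arange(n_units)
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
        null[it] = total_correlation(Aw, Bw[perm]).rho2
    p = float((1 + np.sum(null >= obs)) / (1 + n))
    return {"observed": obs, "null": null, "p": p}


def partial_total_correlation(A: PcWeights | np.ndarray, B: PcWeights | np.ndarray, factor) -> TotalCorrelation:
    """Total correlation with every off-diagonal entry replaced by the
    partial correlation controlling for the per-unit factor f:
    r_ij|f = (r_ij - r_if r_jf) / (sqrt(1 - r_if^2) sqrt(1 - r_jf^2)).
    """
    Aw = A.weights if isinstance(A, PcWeights) else np.asarray(A, float)
    Bw = B.weights if isinstance(B, PcWeights) else np.asarray(B, float)
    f = np.asarray(factor, float)
    if not np.all(np.isfinite(f)):
        raise ValueError("factor must be finite for every unit")
    if f.std() == 0:
        raise ValueError("constant factor: partial correlation undefined")
    W = np.hstack([Aw, Bw])
    C = _stacked_corr(Aw, Bw)
    rf = np.array([stats.pearsonr(W[:, k], f)[0] for k in range(W.shape[1])])
    if np.any(np.abs(rf) >= 1.0 - 1e-12):
        raise ValueError("factor perfectly correlated with a weight column")
    denom = np.sqrt(1.0 - rf**2)
    Cp = (C - np.outer(rf, rf)) / np.outer(denom, denom)
    np.fill_diagonal(Cp, 1.0)
    rho2 = float(np.clip(1.0 - _corr_det(Cp), 0.0, 1.0))
    return TotalCorrelation(C=Cp, rho2=rho2)


def modulation_strength_correlation(theta_depths, swr_energies) -> tuple[float, float]:
    """Pearson correlation between per-unit theta modulation depth and SWR
    energy."""
    x = np.asarray(theta_depths, float)
    y = np.asarray(swr_energies, float)
    if x.size != y.size:
        raise ValueError("inputs must be paired per unit")
    if x.size < 3:
        raise ValueError("need at least 3 units")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classification_score(c, c_hat, c_hat_s) -> float:
    """Shuffle-referenced classification score
    s = (sum 1(c = c_hat) - sum 1(c = c_hat_s)) / (N - sum 1(c = c_hat_s)).

    0 is chance level (relative to the shuffle classifier), 1 is perfect;
    negative values mean worse than shuffle.
    """
    c = np.asarray(c)
    c_hat = np.asarray(c_hat)
    c_hat_s = np.asarray(c_hat_s)
    if not (c.shape == c_hat.shape == c_hat_s.shape):
        raise ValueError("label vectors must have equal length")
    n = c.size
    correct = int(np.sum(c == c_hat))
    correct_s = int(np.sum(c == c_hat_s))
    if correct_s == n:
        raise ValueError("shuffle classifier is perfect: score undefined (division by zero)")
    return float((correct - correct_s) / (n - correct_s))


def _cv_predict(X, y, folds, n_iter, seed) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold predictions of a gradient-boosted tree classifier."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    accs = []
    for tr, te in skf.split(X, y):
        clf = HistGradientBoostingClassifier(max_iter=n_iter, early_stopping=False, random_state=seed)
        clf.fit(X[tr], y[tr])
        pred[te] = clf.predict(X[te])
        accs.append(float(np.mean(pred[te] == y[te])))
    return pred, np.array(accs)


def train_hd_classifier(
    X: np.ndarray,
    labels,
    max_lags_s=(0.040,),
    bin_s: float = 0.0005,
    feat_start_s: float = 0.002,
    n_states: int = 3,
    n_iter: int = 1000,
    folds: int = 10,
    n_shuffles: int = 5,
    seed: int = 0,
) -> list[ScoreReport]:
    """Classify HD vs non-HD units from stacked auto-correlograms.

    `X` holds per-unit stacked features (n_states blocks of lag bins from
    `feat_start_s` up to the largest max_lag, at `bin_s`). For each max_lag
    in `max_lags_s` the blocks are truncated, a gradient-boosted tree
    classifier is cross-validated, and the score is referenced against a
    classifier trained on label-shuffled data (the shuffle run with the
    median correct-count provides the reference prediction vector).
    """
    X = np.asarray(X, float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    block = X.shape[1] // n_states
    reports = []
    for max_lag in max_lags_s:
        n_keep = int(round((max_lag - feat_start_s) / bin_s))
        if n_keep < 1:
            raise ValueError("max_lag must be at least one bin above feat_start_s")
        n_keep = min(n_keep, block)
        cols = np.concatenate([np.arange(s * block, s * block + n_keep) for s in range(n_states)])
        Xl = X[:, cols]
        pred, accs = _cv_predict(Xl, y, folds, n_iter, seed)
        shuffle_preds, shuffle_correct = [], []
        for k in range(n_shuffles):
            rng = stream(seed, f"label-shuffle-{k}")
            y_sh = y[rng.permutation(y.size)]
            pred_s, _ = _cv_predict(Xl, y_sh, folds, n_iter, seed + 1 + k)
            shuffle_preds.append(pred_s)
            shuffle_correct.append(int(np.sum(pred_s == y)))
        shuffle_correct = np.array(shuffle_correct)
        rep_idx = int(np.argsort(shuffle_correct)[len(shuffle_correct) // 2])
        c_hat_s = shuffle_preds[rep_idx]
        # the chance reference is the mean correct-count across shuffle runs
        correct = int(np.sum(pred == y))
        mean_cs = float(shuffle_correct.mean())
        if mean_cs >= y.size:
            raise ValueError("shuffle classifiers are perfect: score undefined")
        s = float((correct - mean_cs) / (y.size - mean_cs))
        reports.append(
            ScoreReport(
                score=s,
                max_lag_s=float(max_lag),
                labels=y,
                predictions=pred,
                shuffle_predictions=c_hat_s,
                fold_accuracies=accs,
                shuffle_accuracies=shuffle_correct,
            )
        )
    return reports
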