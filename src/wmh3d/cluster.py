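"""Feature reduction, multi-restart K-means and gap-statistic model selection.

The descriptor/texture features are reduced by PCA (keeping a fixed fraction
of variance), clustered with Lloyd's K-means restarted from many random
row-draws (the lowest within-cluster dispersion ``W_k`` wins), and the
number of clusters is chosen by the gap statistic: ``W_k`` on the data is
compared against ``W_k`` on uniform reference draws from the data's
bounding box, and the selected ``k`` is the smallest one with
``Gap(k) >= Gap(k+1) - s_{k+1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ClusterModel",
    "GapCurve",
    "pca_reduce",
    "within_dispersion",
    "kmeans_best_of",
    "gap_statistic",
    "select_k_hat",
    "representatives",
]


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    W_k: float


@dataclass
class GapCurve:
    """Per-k gap-statistic summary and the selected cluster count."""

    ks: np.ndarray
    W_k: np.ndarray
    log_W_ref_mean: np.ndarray
    gap: np.ndarray
    sd_k: np.ndarray
    s_k: np.ndarray
    k_hat: int
    B: int


def pca_reduce(features: np.ndarray, variance_retained: float = 0.998) -> np.ndarray:
    """Mean-centred PCA scores keeping the fewest components whose
    cumulative explained variance reaches the threshold (at least one)."""
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not 0 < variance_retained <= 1:
        raise ValueError("variance_retained must be in (0, 1]")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    n_comp = min(max(n_comp, 1), scores.shape[1])
    return scores[:, :n_comp]


def within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of squared distances to the cluster mean."""
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        w += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return w


def kmeans_best_of(
    features: np.ndarray,
    k: int,
    trials: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ClusterModel:
    """Best-of-``trials`` K-means: each trial starts Lloyd iteration from
    ``k`` rows drawn uniformly without replacement; lowest ``W_k`` wins."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of observations")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == 1:
        mu = x.mean(axis=0, keepdims=True)
        return ClusterModel(1, np.zeros(n, dtype=int), mu, float(np.sum((x - mu) ** 2)))
    best: ClusterModel | None = None
    for _ in range(trials):
        init = x[rng.choice(n, size=k, replace=False)]
        with warnings.catch_warnings():
            # duplicate rows can collapse clusters; the restart scheme
            # already covers that, so the per-fit warning is noise
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, init=init, n_init=1, algorithm="lloyd").fit(x)
        w = within_dispersion(x, km.labels_)
        if best is None or w < best.W_k:
            best = ClusterModel(k, km.labels_.copy(), km.cluster_centers_.copy(), w)
    return best


def gap_statistic(
    features: np.ndarray,
    N: int = 20,
    B: int = 30,
    seed: int | np.random.Generator = 0,
    trials_per_fit: int = 10,
) -> GapCurve:
    """Gap-statistic curve over k = 1..N with B uniform reference draws.

    References are sampled uniformly within the per-dimension bounding box
    of the data.  ``s_k = sd_k * sqrt(1 + 1/B)`` and the selected cluster
    count is the smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}`` (falling
    back to N if no k qualifies).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if N < 2 or B < 2:
        raise ValueError("need N >= 2 and B >= 2")
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("degenerate bounding box")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.shape[0]
    N = min(N, n - 1)  # k = n gives W_k = 0 identically; nothing to compare
    if N < 2:
        raise ValueError("too few observations for a gap curve")
    ks = np.arange(1, N + 1)
    tiny = np.finfo(float).tiny
    w_k = np.array(
        [kmeans_best_of(x, k, trials=trials_per_fit, seed=rng).W_k for k in ks]
    )
    log_w_ref = np.empty((B, N))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        for i, k in enumerate(ks):
            log_w_ref[b, i] = np.log(
                max(kmeans_best_of(ref, k, trials=trials_per_fit, seed=rng).W_k, tiny)
            )
    mean_ref = log_w_ref.mean(axis=0)
    gap = mean_ref - np.log(np.maximum(w_k, tiny))
    sd_k = log_w_ref.std(axis=0)  # population SD over the B references
    s_k = sd_k * np.sqrt(1.0 + 1.0 / B)
    k_hat = select_k_hat(gap, s_k, ks)
    return GapCurve(ks, w_k, mean_ref, gap, sd_k, s_k, k_hat, B)


def select_k_hat(gap: np.ndarray, s_k: np.ndarray, ks: np.ndarray | None = None) -> int:
    """Smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}`` (last k if none)."""
    ks = np.arange(1, len(gap) + 1) if ks is None else np.asarray(ks)
    for i in range(len(gap) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            return int(ks[i])
    return int(ks[-1])


def representatives(
    model: ClusterModel, features: np.ndarray, per_cluster: int = 4
) -> dict[int, list[int]]:
    """Per cluster: row indices closest to the centroid, ascending distance,
    ties broken by row index.  Small clusters return all members."""
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    out: dict[int, list[int]] = {}
    for c in range(model.k):
        rows = np.nonzero(model.assignments == c)[0]
        d = np.linalg.norm(x[rows] - model.centroids[c], axis=1)
        order = np.lexsort((rows, d))
        out[c] = [int(rows[i]) for i in order[:per_cluster]]
    return out
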