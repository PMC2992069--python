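"""k-means clustering of score vectors and gap-statistic model selection.

The number of hidden states for the HMM is chosen as an initial guess by
clustering the m-dimensional gene score vectors with k-means and picking the
cluster number K that maximises the gap statistic

    Gap(K) = E[log(W_K)] - log(W*_K),

where W*_K is the pooled within-cluster sum of squares of the observed data
and the expectation is a Monte-Carlo mean of log(W_K) over reference datasets
drawn uniformly over each feature's observed range (Tibshirani's simplest
reference distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .scores import GeneScoreMatrix

__all__ = ["ClusterModel", "GapResult", "kmeans_fit", "gap_statistic"]


def _as_array(scores) -> np.ndarray:
    if isinstance(scores, GeneScoreMatrix):
        return scores.scores
    return np.asarray(scores, dtype=float)


@dataclass
class ClusterModel:
    """A fitted k-means partition of the gene score vectors."""

    K: int
    assignments: np.ndarray  # (n,) labels in {0..K-1}
    centers: np.ndarray  # (K, m)
    within_ss: float  # pooled within-cluster sum of squares W*_K
    per_cluster_variance: np.ndarray  # (K, m), MLE (divide-by-n) variances

    def occupancy(self) -> np.ndarray:
        counts = np.bincount(self.assignments, minlength=self.K).astype(float)
        return counts / counts.sum()


@dataclass
class GapResult:
    k_values: np.ndarray
    gap: np.ndarray
    expected_logW: np.ndarray
    observed_logW: np.ndarray
    n_boot: int
    best_k: int


def kmeans_fit(scores, K: int, seed: int = 0, n_restart: int = 10) -> ClusterModel:
    """Lloyd k-means with ``n_restart`` random initialisations (best kept).

    Deterministic given ``seed``.  K = n gives a zero within-cluster sum of
    squares; K > n raises.
    """
    X = _as_array(scores)
    n, m = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of points n={n}")
    km = KMeans(n_clusters=K, n_init=n_restart, random_state=seed)
    labels = km.fit_predict(X)
    variances = np.empty((K, m))
    for k in range(K):
        members = X[labels == k]
        if not len(members):  # unreachable with sklearn, kept as a guard
            raise ValueError(f"cluster {k} is empty")
        variances[k] = members.var(axis=0)
    return ClusterModel(
        K=K,
        assignments=labels,
        centers=km.cluster_centers_,
        within_ss=float(km.inertia_),
        per_cluster_variance=variances,
    )


def gap_statistic(
    scores,
    k_range=range(1, 9),
    n_boot: int = 1000,
    seed: int = 0,
    n_restart: int = 10,
    sample_size: int | None = None,
) -> GapResult:
    """Gap-statistic selection of the cluster number.

    Reference datasets are drawn uniformly over the observed per-feature
    ranges; ``best_k`` is the K in ``k_range`` with the largest gap.
    ``sample_size`` subsamples the rows (without replacement) before the whole
    computation, trading precision for speed on large gene sets.
    """
    X = _as_array(scores)
    rng = np.random.default_rng(seed)
    if sample_size is not None and sample_size < len(X):
        X = X[rng.choice(len(X), size=sample_size, replace=False)]
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all rows identical, W_K = 0")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    k_values = np.asarray(list(k_range), dtype=int)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def log_w(data: np.ndarray, k: int, km_seed: int) -> float:
        return float(np.log(kmeans_fit(data, k, seed=km_seed, n_restart=n_restart).within_ss))

    observed = np.array([log_w(X, int(k), seed) for k in k_values])
    boot_logW = np.empty((n_boot, len(k_values)))
    for b in range(n_boot):
        ref = rng.uniform(lo, hi, size=X.shape)
        km_seed = int(rng.integers(2**31 - 1))
        for j, k in enumerate(k_values):
            boot_logW[b, j] = log_w(ref, int(k), km_seed)
    expected = boot_logW.mean(axis=0)
    gap = expected - observed
    return GapResult(
        k_values=k_values,
        gap=gap,
        expected_logW=expected,
        observed_logW=observed,
        n_boot=n_boot,
        best_k=int(k_values[int(np.argmax(gap))]),
    )
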