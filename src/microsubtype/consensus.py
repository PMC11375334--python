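"""Resampling-based consensus clustering with PAC model selection.

For each candidate cluster number K, the sample set is repeatedly
subsampled (fraction ``p_item`` of samples, ``p_feature`` of features,
without replacement), k-means with Euclidean distance partitions each
subsample, and two tallies accumulate per sample pair: how often the pair
was drawn together (co-sample count) and how often it then landed in the
same cluster (co-cluster count).  The consensus matrix is their elementwise
ratio — near 0/1 everywhere when the partition is stable.  Final labels
come from average-linkage hierarchical clustering of 1 - consensus.

The proportion of ambiguous clustering (PAC) is the mass of the consensus
CDF inside an ambiguity window (default (0.1, 0.9)); the best K minimizes
PAC, ties going to the smaller K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans


@dataclass
class ConsensusRun:
    """One consensus-clustering run at a fixed K."""

    K: int
    reps: int
    consensus: np.ndarray          # n x n, entries in [0, 1]
    cosample_counts: np.ndarray    # n x n integer tallies
    labels: np.ndarray             # final assignment, values 1..K
    seed: int
    retries: int = 0               # k-means reps redone for empty clusters

    @property
    def n_samples(self) -> int:
        return self.consensus.shape[0]

    def upper_triangle(self, visited_only: bool = True) -> np.ndarray:
        """Pairwise consensus entries i < j (optionally only co-sampled pairs)."""
        iu = np.triu_indices(self.n_samples, k=1)
        vals = self.consensus[iu]
        if visited_only:
            vals = vals[self.cosample_counts[iu] > 0]
        return vals


@dataclass
class PACProfile:
    """PAC value per candidate K and the selected optimum."""

    pac: dict[int, float]
    x1: float = 0.1
    x2: float = 0.9
    best_k: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.pac:
            raise ValueError("empty PAC profile")
        # argmin with ties resolved toward the smaller K
        self.best_k = min(sorted(self.pac), key=lambda k: (self.pac[k], k))


def _kmeans_labels(X: np.ndarray, K: int, rng: np.random.Generator, n_restarts: int,
                   max_retries: int = 5) -> tuple[np.ndarray, int]:
    """k-means labels with a retry if fewer than K clusters come back."""
    retries = 0
    while True:
        km = KMeans(
            n_clusters=K,
            n_init=n_restarts,
            init="k-means++",
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == K or retries >= max_retries:
            return labels, retries
        retries += 1


def run_consensus(
    X: np.ndarray,
    K: int,
    reps: int = 50,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> ConsensusRun:
    """Consensus k-means at a fixed K (Monti-style resampling estimator).

    ``X`` is a samples x features matrix (relative abundances for the
    subtyping use case).  Per-rep RNG streams derive from the master seed,
    so results are reproducible and independent of execution order.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n_samples, got K={K}, n={n}")
    if not 0 < p_item <= 1 or not 0 < p_feature <= 1:
        raise ValueError("p_item and p_feature must be in (0, 1]")

    n_items = max(K, int(np.floor(p_item * n)))
    n_feats = max(1, int(np.floor(p_feature * m)))
    cocluster = np.zeros((n, n))
    cosample = np.zeros((n, n), dtype=np.int64)
    total_retries = 0

    streams = np.random.SeedSequence(seed).spawn(reps)
    for rep in range(reps):
        rng = np.random.default_rng(streams[rep])
        items = np.sort(rng.choice(n, size=n_items, replace=False))
        feats = (
            np.sort(rng.choice(m, size=n_feats, replace=False))
            if n_feats < m
            else np.arange(m)
        )
        labels, retries = _kmeans_labels(X[np.ix_(items, feats)], K, rng, n_restarts)
        total_retries += retries
        onehot = (labels[:, None] == np.arange(K)[None, :]).astype(float)
        block = onehot @ onehot.T  # 1 where same cluster
        cocluster[np.ix_(items, items)] += block
        cosample[np.ix_(items, items)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    consensus = (consensus + consensus.T) / 2.0  # enforce exact symmetry

    # final labels: average-linkage tree over consensus dissimilarity
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    labels = _relabel_by_size(labels)
    return ConsensusRun(
        K=K,
        reps=reps,
        consensus=consensus,
        cosample_counts=cosample,
        labels=labels,
        seed=seed,
        retries=total_retries,
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..K by decreasing size (ties by old label)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[v] for v in labels], dtype=int)


def consensus_cdf(run: ConsensusRun) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of pairwise consensus entries.

    Returns ``(xs, cdf)`` where ``cdf[i]`` is the fraction of entries
    <= ``xs[i]``; a right-continuous step function with CDF(1) = 1.
    """
    vals = np.sort(run.upper_triangle())
    if vals.size == 0:
        raise ValueError("need at least one co-sampled pair")
    xs, counts = np.unique(vals, return_counts=True)
    return xs, np.cumsum(counts) / vals.size


def cdf_at(run: ConsensusRun, x: float) -> float:
    vals = run.upper_triangle()
    return float(np.mean(vals <= x)) if vals.size else 0.0


def pac(run: ConsensusRun, x1: float = 0.1, x2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: CDF(x2) - CDF(x1).

    The fraction of sample pairs whose consensus value is neither firmly
    together (> x2) nor firmly apart (<= x1).
    """
    if not 0 < x1 < x2 < 1:
        raise ValueError(f"need 0 < x1 < x2 < 1, got ({x1}, {x2})")
    vals = run.upper_triangle()
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > x1) & (vals <= x2)))


def pac_profile(
    X: np.ndarray,
    k_values: range | list[int],
    reps: int = 50,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int = 0,
    x1: float = 0.1,
    x2: float = 0.9,
    n_restarts: int = 10,
) -> tuple[PACProfile, dict[int, ConsensusRun]]:
    """Run consensus clustering over a K grid and select the PAC optimum."""
    runs: dict[int, ConsensusRun] = {}
    values: dict[int, float] = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(len(list(k_values)))
    for child, K in zip(child_seeds, k_values):
        run = run_consensus(
            X, K, reps=reps, p_item=p_item, p_feature=p_feature,
            seed=int(child % (2**31 - 1)), n_restarts=n_restarts,
        )
        runs[K] = run
        values[K] = pac(run, x1, x2)
    return PACProfile(values, x1=x1, x2=x2), runs


def select_best_k(profile: PACProfile) -> int:
    return profile.best_k
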