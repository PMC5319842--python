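"""Cluster-based gene weighting for the weighted-error selection variant.

Co-expressed genes carry redundant information about where the temporal
action is; an unweighted loss lets a large cluster of near-identical
profiles dominate the choice of time points.  Weighting each gene by the
reciprocal of its cluster's size makes every expression *pattern* -- rather
than every gene -- contribute equally to the loss.

Clusters are found by k-means over per-gene temporal feature vectors, with
the number of clusters chosen by the Bayesian Information Criterion under a
hard-assignment spherical Gaussian interpretation (pooled variance; the
x-means-style formulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .data import TimeSeriesDataset
from .selection import SelectionResult, SplineScorer, greedy_search

__all__ = ["ClusterAssignment", "cluster_genes", "weighted_selection"]


@dataclass
class ClusterAssignment:
    """Gene -> cluster map with reciprocal-size weights.

    The weights satisfy ``sum_g w_g = K``: each cluster contributes total
    weight one.
    """

    labels: dict[str, int]
    n_clusters: int
    bic_by_k: dict[int, float]

    @property
    def weights(self) -> dict[str, float]:
        sizes = np.bincount(list(self.labels.values()), minlength=self.n_clusters)
        return {g: 1.0 / sizes[c] for g, c in self.labels.items()}

    def weight_vector(self, gene_ids: list[str]) -> np.ndarray:
        w = self.weights
        missing = [g for g in gene_ids if g not in w]
        if missing:
            raise ValueError(f"assignment does not cover gene(s) {missing[:3]}")
        return np.array([w[g] for g in gene_ids])

    def to_tsv(self) -> str:
        lines = ["gene\tcluster"]
        lines += [f"{g}\t{c}" for g, c in self.labels.items()]
        return "\n".join(lines) + "\n"


def _bic_spherical(features: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a hard-assignment spherical Gaussian mixture (x-means form).

    The mixture has per-cluster means, mixing proportions n_c/N, and a
    pooled variance ``sigma^2 = SS_within / (d (N - K))``; the classified
    log-likelihood is

        lnL = sum_c n_c ln(n_c / N) - (N d / 2) ln(2 pi sigma^2)
              - d (N - K) / 2,

    and BIC = K (d + 1) ln N - 2 lnL (lower is better).  The mixing-
    proportion term matters: without it the criterion over-splits on any
    data, because 2-means can always cut a cluster's within-SS by a
    finite fraction while the ln N penalty stays bounded.
    """
    n, d = features.shape
    ss = 0.0
    for c in range(k):
        members = features[labels == c]
        if members.size:
            ss += float(np.sum((members - members.mean(axis=0)) ** 2))
    sigma2 = max(ss / (d * max(n - k, 1)), 1e-12)
    counts = np.bincount(labels, minlength=k).astype(float)
    loglik = (
        float(np.sum(counts * np.log(np.maximum(counts, 1.0) / n)))
        - 0.5 * n * d * np.log(2 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    n_params = k * (d + 1)
    return n_params * np.log(n) - 2.0 * loglik


def _features(
    ds: TimeSeriesDataset, feature_mode: str, scorer: SplineScorer | None
) -> np.ndarray:
    means = ds.repeat_means()
    if feature_mode == "spline":
        # evaluate each gene's LOOCV-smoothed spline on the full grid at
        # uniformly spaced times (deterministic resampling)
        scorer = scorer or SplineScorer(ds)
        from .splines import natural_eval_matrix, natural_spline_system

        x = ds.grid.times
        uniform = np.linspace(x[0], x[-1], x.size)
        K, rinv_qt = natural_spline_system(x)
        A = natural_eval_matrix(x, rinv_qt, uniform)
        hbar = float(np.mean(np.diff(x)))
        eye = np.eye(x.size)
        feats = np.empty_like(means)
        cv = np.full((scorer.lam_grid.size, means.shape[0]), np.inf)
        fits = np.empty((scorer.lam_grid.size, means.shape[0], uniform.size))
        for j, lam in enumerate(scorer.lam_grid * hbar**3):
            H = np.linalg.solve(eye + lam * K, eye)
            resid = means - means @ H.T
            denom = np.clip(1.0 - np.diag(H), 1e-12, None)
            cv[j] = np.sum((resid / denom[None, :])[:, 1:-1] ** 2, axis=1)
            fits[j] = means @ (A @ H).T
        choice = cv.shape[0] - 1 - np.argmin(cv[::-1], axis=0)
        feats = fits[choice, np.arange(means.shape[0]), :]
    elif feature_mode == "raw":
        feats = means
    else:
        raise ValueError("feature_mode must be 'raw' or 'spline'")
    # z-normalize per gene so clustering reflects shape, not amplitude
    center = feats.mean(axis=1, keepdims=True)
    scale = feats.std(axis=1, keepdims=True)
    scale[scale <= 1e-12] = 1.0
    return (feats - center) / scale


def cluster_genes(
    ds: TimeSeriesDataset,
    k_range=range(1, 11),
    feature_mode: str = "raw",
    seed: int = 0,
    scorer: SplineScorer | None = None,
) -> ClusterAssignment:
    """Cluster gene trajectories by k-means; choose K by BIC.

    Each gene is a point in R^T (its per-time repeat means, z-scored per
    gene), or its smoothed spline resampled at T uniform times in
    ``spline`` mode.  For each K in ``k_range``, k-means runs with 10
    restarts from the given seed; the K minimizing the spherical-Gaussian
    BIC wins (ties toward fewer clusters).
    """
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 1 or max(k_range) > ds.n_genes:
        raise ValueError("K range must lie within [1, #genes]")
    feats = _features(ds, feature_mode, scorer)
    bic_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(set(k_range)):
        labels = None
        for attempt in range(5):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
            fitted = km.fit_predict(feats)
            if len(np.unique(fitted)) == k:
                labels = fitted
                break
        if labels is None:
            raise RuntimeError(f"k-means produced an empty cluster for K={k}")
        labels_by_k[k] = labels
        bic_by_k[k] = _bic_spherical(feats, labels, k)
    best_k = min(sorted(bic_by_k), key=bic_by_k.get)
    return ClusterAssignment(
        labels=dict(zip(ds.gene_ids, (int(c) for c in labels_by_k[best_k]))),
        n_clusters=best_k,
        bic_by_k=bic_by_k,
    )


def weighted_selection(
    ds: TimeSeriesDataset,
    k: int,
    assignment: ClusterAssignment,
    init="abs",
    max_iter: int = 100,
    multi_swap: bool = False,
) -> SelectionResult:
    """Greedy selection under cluster-reciprocal gene weights."""
    weights = assignment.weight_vector(ds.gene_ids)
    result = greedy_search(
        ds, k, init=init, weights=weights, max_iter=max_iter, multi_swap=multi_swap
    )
    result.search_method = "greedy(weighted)"
    return result
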