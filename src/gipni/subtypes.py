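"""Perturbation-subtype discovery by consensus clustering.

Monti-style consensus clustering of tumor samples on the edge
perturbation matrix: repeated subsampling, partitioning-around-medoids
on a 1 - Spearman-correlation distance over edge features, and
co-assignment accumulation.  The optimal cluster number is chosen from
the consensus CDF delta-area curve; final labels come from hierarchical
clustering of 1 - consensus.  A k-group log-rank test compares subtype
survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import TUMOR, SurvivalTable
from .perturbation import EdgePerturbationMatrix


@dataclass
class ConsensusResult:
    """Output of consensus clustering over a range of cluster numbers."""

    k_range: list[int]
    consensus_matrices: dict[int, pd.DataFrame]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (x grid, CDF values)
    area: dict[int, float]
    delta_area: dict[int, float]
    optimal_k: int
    labels: dict[int, pd.Series] = field(default_factory=dict)

    def optimal_labels(self) -> pd.Series:
        return self.labels[self.optimal_k]


def spearman_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between columns of X."""
    ranks = rankdata(X, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=0, keepdims=True))
    norm[norm == 0] = 1.0
    ranks = ranks / norm
    corr = ranks.T @ ranks
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def pam_cluster(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic: greedy BUILD initialization followed by Voronoi
    iteration (assign to nearest medoid, re-center each cluster on the
    point minimizing its within-cluster distance sum).
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    # BUILD: first medoid minimizes total distance; then greedily add
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids_arr], axis=1)
        new_medoids = medoids_arr.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            sub = dist[np.ix_(members, members)]
            new_medoids[c] = members[int(np.argmin(sub.sum(axis=1)))]
        if np.array_equal(new_medoids, medoids_arr):
            break
        medoids_arr = np.sort(new_medoids)
    return np.argmin(dist[:, medoids_arr], axis=1)


def _cdf_and_area(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of the upper-triangle consensus entries and its area."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    m = vals.size
    # area under the empirical CDF over [0, 1]
    grid = np.concatenate([[0.0], vals, [1.0]])
    cdf_at = np.concatenate([[0.0], (np.arange(1, m + 1)) / m, [1.0]])
    area = float(np.sum(np.diff(grid) * cdf_at[:-1])) + 0.0
    # report CDF on the sorted support for plotting/inspection
    return grid, cdf_at, area


def consensus_cluster(
    epm: EdgePerturbationMatrix,
    k_range: range | list[int] = range(2, 7),
    n_resamples: int = 200,
    subsample_frac: float = 0.8,
    seed: int = 17,
    elbow_threshold: float = 0.1,
    top_n_edges: int | None = None,
) -> ConsensusResult:
    """Consensus clustering of tumor samples on edge perturbation values.

    Per resample, ``subsample_frac`` of the tumor samples are drawn
    without replacement and clustered by PAM on the (precomputed)
    1 - Spearman distance; consensus entries are co-clustering counts
    divided by co-sampling counts.  ``optimal_k`` is the largest k whose
    relative CDF-area gain over k-1 still exceeds ``elbow_threshold``
    (the first k below the threshold ends the scan).  Final labels per
    k come from average-linkage hierarchical clustering of
    1 - consensus.

    ``top_n_edges`` optionally restricts the features to the most
    variable edges to bound runtime.
    """
    ks = sorted(set(int(k) for k in k_range))
    if epm.tissue_class is not None:
        samples = epm.samples_of_class(TUMOR)
    else:
        samples = epm.sample_ids
    n = len(samples)
    if not ks or ks[0] < 2 or ks[-1] > n // 3:
        raise ValueError(f"k_range must lie within [2, n/3] = [2, {n // 3}]")
    X = epm.values[samples].to_numpy(dtype=float)
    if top_n_edges is not None and top_n_edges < X.shape[0]:
        var = X.var(axis=1)
        keep = np.argsort(var)[::-1][:top_n_edges]
        X = X[keep]
    dist = spearman_distance(X)

    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_frac * n)), max(ks) + 1)
    subsamples = [
        rng.choice(n, size=n_sub, replace=False) for _ in range(n_resamples)
    ]

    consensus_matrices: dict[int, pd.DataFrame] = {}
    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    area: dict[int, float] = {}
    labels: dict[int, pd.Series] = {}
    for k in ks:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for idx in subsamples:
            sub_dist = dist[np.ix_(idx, idx)]
            assign = pam_cluster(sub_dist, k)
            sampled[np.ix_(idx, idx)] += 1.0
            for c in range(k):
                members = idx[assign == c]
                together[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore"):
            cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus_matrices[k] = pd.DataFrame(cons, index=samples, columns=samples)
        grid, cdf_vals, a = _cdf_and_area(cons)
        cdf[k] = (grid, cdf_vals)
        area[k] = a
        link = linkage(squareform(1.0 - cons, checks=False), method="average")
        labels[k] = pd.Series(fcluster(link, t=k, criterion="maxclust"), index=samples)

    delta_area: dict[int, float] = {ks[0]: area[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        delta_area[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else 0.0
    optimal_k = ks[0]
    for k in ks[1:]:
        if delta_area[k] >= elbow_threshold:
            optimal_k = k
        else:
            break
    return ConsensusResult(
        k_range=ks,
        consensus_matrices=consensus_matrices,
        cdf=cdf,
        area=area,
        delta_area=delta_area,
        optimal_k=optimal_k,
        labels=labels,
    )


def logrank_by_label(surv: SurvivalTable, labels: pd.Series) -> tuple[float, float]:
    """k-group log-rank test of survival differences between labels.

    Returns the chi-square statistic and p-value; ties are handled by
    the standard hypergeometric variance formula.
    """
    shared = surv.data.index.intersection(labels.index)
    labels = labels.loc[shared]
    data = surv.data.loc[shared]
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for g in groups:
        if (data.loc[labels == g, "event"] == 1).sum() < 1:
            raise ValueError(f"group {g!r} has no events")
    res = multivariate_logrank_test(data["time"], labels, data["event"])
    return float(res.test_statistic), float(res.p_value)
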