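"""Per-cohort subtype discovery by dual-algorithm consensus clustering.

Two unsupervised algorithms — Ward.D2 agglomerative clustering on Euclidean
distances and k-means — are applied to the covariate-adjusted methylation
profiles of the disease samples of one cohort. The cluster count is chosen by
the elbow of the within-cluster sum-of-squares curve per algorithm and then
arbitrated across algorithms by normalized mutual information (NMI); samples
on which the two algorithms disagree after optimal label alignment are marked
inconsistent and excluded from subtype membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "SubtypeAssignment",
    "cluster_hierarchical",
    "cluster_kmeans",
    "wcss",
    "elbow_select",
    "nmi",
    "consensus_k",
    "consensus_labels",
]

#: consensus label used for samples the two algorithms disagree on
INCONSISTENT = 0


@dataclass
class SubtypeAssignment:
    """Dual-algorithm clustering result for one cohort.

    Labels are integers 1..k in canonical order (decreasing cluster size);
    ``consensus`` is the aligned label where both algorithms agree and
    ``INCONSISTENT`` (0) otherwise.
    """

    hierarchical: np.ndarray
    kmeans: np.ndarray
    consensus: np.ndarray
    k: int
    nmi_by_k: dict[int, float] = field(default_factory=dict)
    cohort: str = ""
    sample_ids: list[str] = field(default_factory=list)

    def consistent_mask(self) -> np.ndarray:
        return self.consensus != INCONSISTENT


def _as_obs_matrix(x) -> np.ndarray:
    """Accept samples x features array/DataFrame; return float ndarray."""
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Rename clusters 1..k by decreasing size (ties by first appearance).

    Cluster names carry no meaning, so a deterministic size ordering replaces
    any arbitrary labelling and makes runs reproducible.
    """
    labels = np.asarray(labels)
    uniq, first = np.unique(labels, return_index=True)
    sizes = np.array([(labels == u).sum() for u in uniq])
    order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], first[i]))
    mapping = {uniq[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def cluster_hierarchical(x, k: int) -> np.ndarray:
    """Ward.D2 agglomerative clustering, tree cut at k clusters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = _as_obs_matrix(x)
    if k > obs.shape[0]:
        raise ValueError("k exceeds the number of samples")
    z = linkage(obs, method="ward")  # scipy ward == Ward.D2 on Euclidean input
    return _canonicalize(fcluster(z, t=k, criterion="maxclust"))


def cluster_kmeans(x, k: int, seed: int = 0, n_init: int = 25) -> np.ndarray:
    """Best-of-``n_init`` k-means++ labelling (seed-deterministic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    obs = _as_obs_matrix(x)
    if k > obs.shape[0]:
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(obs)
    return _canonicalize(km.labels_)


def wcss(x, labels: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances to cluster means."""
    obs = _as_obs_matrix(x)
    total = 0.0
    for lab in np.unique(labels):
        sub = obs[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def elbow_select(
    x,
    k_range,
    algorithm: str = "hierarchical",
    seed: int = 0,
    n_init: int = 25,
    weak_rel_tol: float = 0.25,
):
    """Choose k at the elbow of the WCSS curve.

    The elbow is formalized as the k maximizing the second difference of the
    WCSS curve over the interior of ``k_range`` (ties broken to the smallest
    k). Returns ``(k, curve, weak)`` where ``curve`` maps k to WCSS for audit
    and ``weak`` flags a flat curve with no pronounced elbow: the maximal
    second difference below ``weak_rel_tol`` of the total WCSS drop (clustered
    structure produces relative curvature near 0.5; unstructured noise stays
    well under 0.2).
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if ks != list(range(min(ks), max(ks) + 1)) or min(ks) < 1:
        raise ValueError("k_range must be contiguous with min >= 1")
    fit = (
        (lambda k: cluster_hierarchical(x, k))
        if algorithm == "hierarchical"
        else (lambda k: cluster_kmeans(x, k, seed=seed, n_init=n_init))
    )
    curve = {k: wcss(x, fit(k)) for k in ks}
    w = np.array([curve[k] for k in ks])
    second = w[:-2] - 2.0 * w[1:-1] + w[2:]  # indexed by interior ks
    best = int(np.argmax(second))
    k_sel = ks[1 + best]
    total_drop = max(w[0] - w[-1], 0.0)
    weak = total_drop <= 0 or second[best] < weak_rel_tol * total_drop
    return k_sel, curve, weak


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a, b) -> float:
    """Normalized mutual information, normalized by the average entropy.

    Invariant to renaming of cluster labels; 1.0 iff the partitions are equal
    up to renaming; 0.0 when the joint distribution factorizes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    n = joint.sum()
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    mask = pij > 0
    mi = float((pij[mask] * np.log(pij[mask] / np.outer(pi, pj)[mask])).sum())
    ha, hb = _entropy(joint.sum(axis=1)), _entropy(joint.sum(axis=0))
    denom = 0.5 * (ha + hb)
    if denom == 0.0:
        return 1.0  # both partitions trivial, hence identical
    v = mi / denom
    # snap floating-point residue at the exact endpoints
    if abs(v) < 1e-12:
        v = 0.0
    if abs(v - 1.0) < 1e-12:
        v = 1.0
    return max(0.0, min(1.0, v))


def consensus_k(x, k_range, seed: int = 0, n_init: int = 25):
    """Cluster-count arbitration: argmax_k NMI(hierarchical_k, kmeans_k).

    Returns ``(k, nmi_by_k)``; ties go to the smallest k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    table = {}
    for k in ks:
        h = cluster_hierarchical(x, k)
        m = cluster_kmeans(x, k, seed=seed, n_init=n_init)
        table[k] = nmi(h, m)
    best = max(ks, key=lambda k: (table[k], -k))
    return best, table


def consensus_labels(
    hier: np.ndarray,
    km: np.ndarray,
    cohort: str = "",
    sample_ids: list[str] | None = None,
    nmi_by_k: dict | None = None,
) -> SubtypeAssignment:
    """Align the two labelings and keep only consistently-labelled samples.

    K-means labels are mapped onto the hierarchical label space by the
    maximum-agreement matching (Hungarian algorithm on the contingency
    table); samples whose aligned labels still disagree get the
    ``INCONSISTENT`` consensus label. The retained count equals the
    contingency-table trace after alignment.
    """
    hier = np.asarray(hier)
    km = np.asarray(km)
    kh, kk = len(np.unique(hier)), len(np.unique(km))
    if kh != kk:
        raise ValueError(f"label sets have different cluster counts ({kh} vs {kk})")
    cont = pd.crosstab(pd.Series(hier), pd.Series(km))
    rows, cols = linear_sum_assignment(-cont.to_numpy())
    mapping = {cont.columns[c]: cont.index[r] for r, c in zip(rows, cols)}
    km_aligned = np.array([mapping[v] for v in km])
    consensus = np.where(hier == km_aligned, hier, INCONSISTENT)
    return SubtypeAssignment(
        hierarchical=hier,
        kmeans=km_aligned,
        consensus=consensus,
        k=kh,
        nmi_by_k=dict(nmi_by_k or {}),
        cohort=cohort,
        sample_ids=list(sample_ids or []),
    )
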