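"""Sample clustering with perturbation-based reproducibility indices.

Samples are clustered hierarchically (Euclidean distance, complete linkage)
and the stability of the k-cluster partition is quantified by re-clustering
Gaussian-perturbed copies of the data:

* **R-index** — for each original cluster, the proportion of its
  within-cluster sample pairs that remain co-clustered after perturbation,
  averaged over clusters and perturbations. 1 means perfectly reproducible.
* **D-index** — for each original cluster, the number of samples omitted
  from plus added to its best-matching perturbed cluster, summed over
  clusters, divided by the cluster count, averaged over perturbations.
  0 means no discrepancy.

With zero noise the perturbation is the identity and R = 1, D = 0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix
from .paired_diffexpr import paired_differences


@dataclass
class Dendrogram:
    """Complete-linkage dendrogram over sample columns."""

    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    sample_ids: list
    metric: str = "euclidean"
    method: str = "complete"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.linkage)
        return [self.sample_ids[i] for i in order]

    def cut(self, k: int) -> np.ndarray:
        """Labels of the k-cluster partition (cut above the n-k lowest merges)."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialise the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return str(self.sample_ids[node.id])
            left, right = node.get_left(), node.get_right()
            ldist = node.dist - left.dist
            rdist = node.dist - right.dist
            return f"({rec(left)}:{ldist:g},{rec(right)}:{rdist:g})"

        return rec(tree) + ";"


@dataclass
class ReproducibilityReport:
    k: int
    r_index: float
    d_index: float
    noise_sd: float
    n_perturb: int
    seed: int | None


def hclust_complete(matrix: ExpressionMatrix | np.ndarray, sample_ids=None) -> Dendrogram:
    """Complete-linkage Euclidean clustering of sample columns.

    Accepts an ExpressionMatrix or a plain genes x samples array. Distances
    are computed between sample columns over all genes. Tied merge distances
    are resolved by lowest observation index (the linkage routine's rule).
    """
    if isinstance(matrix, ExpressionMatrix):
        X = matrix.values.to_numpy(dtype=float)
        sample_ids = matrix.sample_ids
    else:
        X = np.asarray(matrix, dtype=float)
        if sample_ids is None:
            sample_ids = list(range(X.shape[1]))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(pdist(X.T, metric="euclidean"), method="complete")
    return Dendrogram(linkage=Z, sample_ids=list(sample_ids))


def _partition(labels: np.ndarray) -> list[np.ndarray]:
    """Clusters as index arrays, ordered by cluster label."""
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def _r_contribution(orig: list[np.ndarray], labels_pert: np.ndarray) -> float:
    """Mean over original clusters of the preserved within-pair proportion."""
    contribs = []
    for members in orig:
        if members.size < 2:
            continue  # vacuous: no within-cluster pairs
        sub = labels_pert[members]
        same = sum(
            1
            for i in range(members.size)
            for j in range(i + 1, members.size)
            if sub[i] == sub[j]
        )
        contribs.append(same / (members.size * (members.size - 1) / 2))
    if not contribs:  # all-singleton partition: reproducible by convention
        return 1.0
    return float(np.mean(contribs))


def _d_contribution(orig: list[np.ndarray], labels_pert: np.ndarray) -> float:
    """(Omitted + added) w.r.t. best-matching perturbed clusters, per cluster."""
    pert = _partition(labels_pert)
    total = 0
    for members in orig:
        overlaps = [np.intersect1d(members, q).size for q in pert]
        best = int(np.argmax(overlaps))  # argmax takes the smaller index on ties
        overlap = overlaps[best]
        omitted = members.size - overlap
        added = pert[best].size - overlap
        total += omitted + added
    return total / len(orig)


def r_d_indices(
    matrix: ExpressionMatrix | np.ndarray,
    k: int,
    noise_sd: float | None = None,
    n_perturb: int = 100,
    seed: int | None = None,
) -> ReproducibilityReport:
    """Perturbation-based R (reproducibility) and D (discrepancy) indices.

    Each perturbation adds i.i.d. Normal(0, noise_sd^2) noise to every matrix
    entry, re-clusters, and compares the k-cluster partitions. When
    `noise_sd` is None it defaults to the median over genes of the
    within-pair difference standard deviation (a data-driven noise scale;
    requires an ExpressionMatrix with paired metadata).
    """
    if isinstance(matrix, ExpressionMatrix):
        X = matrix.values.to_numpy(dtype=float)
        if noise_sd is None:
            diffs = paired_differences(matrix).to_numpy()
            noise_sd = float(np.median(diffs.std(axis=1, ddof=1)))
    else:
        X = np.asarray(matrix, dtype=float)
        if noise_sd is None:
            raise ValueError("noise_sd must be given for a plain array input")
    n_samples = X.shape[1]
    if not 2 <= k <= n_samples:
        raise ValueError(f"k must lie in [2, {n_samples}]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    base = hclust_complete(X)
    labels0 = base.cut(k)
    orig = _partition(labels0)

    rng = np.random.default_rng(seed)
    r_vals = np.empty(n_perturb)
    d_vals = np.empty(n_perturb)
    for b in range(n_perturb):
        Xp = X + rng.normal(0.0, noise_sd, size=X.shape) if noise_sd > 0 else X
        labels_p = hclust_complete(Xp).cut(k)
        r_vals[b] = _r_contribution(orig, labels_p)
        d_vals[b] = _d_contribution(orig, labels_p)
    return ReproducibilityReport(
        k=k,
        r_index=float(r_vals.mean()),
        d_index=float(d_vals.mean()),
        noise_sd=float(noise_sd),
        n_perturb=n_perturb,
        seed=seed,
    )
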