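"""Clustering of biomolecules by their adsorption free-energy profiles.

Molecules are points in material-space (one coordinate per nanomaterial,
all in kJ/mol, so no standardization is applied).  The module provides the
Euclidean/RMS distance matrix, Ward agglomerative clustering with a
cuttable merge tree, K-means with the inertia elbow curve, PCA variance
profiles for estimating the number of clusters, and selection of one
representative ("probe") molecule per cluster — the member closest to its
cluster centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix_io import FreeEnergyMatrix

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "Partition",
    "VarianceProfile",
    "ElbowCurve",
    "molecule_distance_matrix",
    "ward_linkage",
    "cut_tree",
    "kmeans_partition",
    "elbow_curve",
    "pca_variance",
    "select_representatives",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between labelled items."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage form.

    ``Z[i] = (cluster_a, cluster_b, height, size)`` with leaves 0..n-1 and
    the i-th merge creating cluster n+i.  For Ward linkage the heights are
    non-decreasing (monotone dendrogram).
    """

    Z: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.leaf_ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError(f"linkage shape {self.Z.shape} != ({n - 1}, 4)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def merges_as_leaf_sets(self) -> list[frozenset[int]]:
        """For each merge, the set of leaf indices of the newly formed cluster."""
        n = self.n_leaves
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for i, (a, b, _, _) in enumerate(self.Z):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root, _ = hierarchy.to_tree(self.Z, rd=True)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


@dataclass
class Partition:
    """Flat clustering: one integer label per item, labels 0..k-1 all non-empty."""

    ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.ids),):
            raise ValueError("one label per item required")
        distinct = np.unique(self.labels)
        if not np.array_equal(distinct, np.arange(len(distinct))):
            # normalize to 0..k-1 in order of first appearance
            _, self.labels = np.unique(self.labels, return_inverse=True)

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]


@dataclass
class VarianceProfile:
    """PCA explained-variance ratios and an estimated component count."""

    explained_variance_ratio: np.ndarray
    n_components_estimate: int


@dataclass
class ElbowCurve:
    """K-means inertia (within-cluster sum of squares) versus k."""

    k_values: np.ndarray
    inertia: np.ndarray

    def suggest_k(self) -> int:
        """Elbow suggestion: the point furthest below the chord between the
        curve's endpoints (a knee-point detector robust to a steep first drop).
        """
        if len(self.k_values) < 3:
            return int(self.k_values[np.argmin(self.inertia)])
        x = (self.k_values - self.k_values[0]) / (self.k_values[-1] - self.k_values[0])
        span = self.inertia[0] - self.inertia[-1]
        if span <= 0:
            return int(self.k_values[0])
        y = (self.inertia - self.inertia[-1]) / span
        return int(self.k_values[int(np.argmax((1 - x) - y))])


def molecule_distance_matrix(m: FreeEnergyMatrix, rms: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances between molecule profiles.

    ``rms=True`` divides by sqrt(n_materials) (root-mean-square distance),
    a global rescaling that changes dendrogram heights but no merge order.
    """
    d = squareform(pdist(m.values, metric="euclidean"))
    if rms:
        d = d / np.sqrt(m.n_materials)
    return DistanceMatrix(ids=list(m.molecule_ids), d=d)


def ward_linkage(d: DistanceMatrix) -> LinkageTree:
    """Ward agglomerative clustering from a (Euclidean-derived) distance matrix.

    Merges, at each step, the pair of clusters whose union minimally
    increases the total within-cluster sum of squares, via Lance-Williams
    updates on the pairwise distances; heights follow the convention
    height = sqrt(2 * delta-SSE), which for two singletons equals their
    Euclidean distance.
    """
    if len(d.ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(d.condensed(), method="ward")
    return LinkageTree(Z=Z, leaf_ids=list(d.ids))


def ward_linkage_molecules(m: FreeEnergyMatrix, rms: bool = False) -> LinkageTree:
    """Ward tree over molecules (rows) of a free-energy matrix."""
    return ward_linkage(molecule_distance_matrix(m, rms=rms))


def cut_tree(t: LinkageTree, k: int) -> Partition:
    """Partition into k clusters by undoing the last k-1 merges."""
    if not 1 <= k <= t.n_leaves:
        raise ValueError(f"k={k} out of range [1, {t.n_leaves}]")
    labels = hierarchy.fcluster(t.Z, t=k, criterion="maxclust") - 1
    return Partition(ids=list(t.leaf_ids), labels=labels)


def kmeans_partition(
    m: FreeEnergyMatrix,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> tuple[Partition, float]:
    """Best-of-restarts K-means over molecule profiles; returns (partition, inertia)."""
    if k > m.n_molecules:
        raise ValueError(f"k={k} exceeds number of molecules {m.n_molecules}")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(m.values)
    return Partition(ids=list(m.molecule_ids), labels=km.labels_), float(km.inertia_)


def elbow_curve(
    m: FreeEnergyMatrix, k_max: int = 8, n_restarts: int = 10, seed: int = 0
) -> ElbowCurve:
    """Inertia versus k for k = 1..k_max (non-increasing for best-of-restarts)."""
    ks = np.arange(1, min(k_max, m.n_molecules) + 1)
    inertia = np.array([kmeans_partition(m, int(k), n_restarts, seed)[1] for k in ks])
    return ElbowCurve(k_values=ks, inertia=inertia)


def pca_variance(m: FreeEnergyMatrix) -> VarianceProfile:
    """Explained variance per principal component of the centered matrix.

    The component-count estimate uses Minka's MLE where applicable and
    falls back to the number of components needed to reach 95% of the
    variance when the MLE is undefined (e.g. near-degenerate spectra).
    """
    if m.n_molecules < 2:
        raise ValueError("need at least 2 molecules")
    X = m.values
    if np.allclose(X, X.mean(axis=0)):  # identical rows: rank 0 after centering
        k = min(m.n_molecules, m.n_materials)
        return VarianceProfile(explained_variance_ratio=np.zeros(k), n_components_estimate=0)
    ratios = PCA().fit(X).explained_variance_ratio_
    try:
        n_mle = int(PCA(n_components="mle").fit(X).n_components_)
    except Exception:
        n_mle = int(np.searchsorted(np.cumsum(ratios), 0.95) + 1)
    return VarianceProfile(explained_variance_ratio=ratios, n_components_estimate=n_mle)


def select_representatives(m: FreeEnergyMatrix, p: Partition) -> list[str]:
    """One probe molecule per cluster: the member closest to the cluster centroid.

    Ties are broken by input (row) order.  Returned in cluster-label order.
    """
    if list(p.ids) != list(m.molecule_ids):
        raise ValueError("partition ids do not match matrix molecules")
    reps = []
    for c in range(p.k):
        idx = np.flatnonzero(p.labels == c)
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        centroid = m.values[idx].mean(axis=0)
        dists = np.linalg.norm(m.values[idx] - centroid, axis=1)
        reps.append(m.molecule_ids[idx[int(np.argmin(dists))]])
    return reps
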