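"""Cohort clustering from the Munkres dissimilarity matrix.

Agglomerative clustering with complete linkage runs directly on the
dissimilarities.  The number of clusters is chosen by the silhouette
criterion, with an elbow curve (within-cluster dispersion
``W(k) = sum_clusters sum_pairs d^2 / |cluster|``) reported for inspection.
Because multiscale bootstrap support needs point coordinates, dissimilarities
are first embedded by classical (Torgerson) multidimensional scaling; the
embedded points are then reclustered (complete linkage, Euclidean) at several
resampling scales and each clade's approximately-unbiased (AU) support is
obtained by fitting ``z(r) = v sqrt(r) + c / sqrt(r)`` to the inverse-normal
transformed bootstrap probabilities, with ``AU = 1 - Phi(v - c)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_samples, silhouette_score

from .similarity import DissimilarityMatrix

__all__ = [
    "ClusterTree",
    "hierarchical_cluster",
    "choose_k",
    "KSelection",
    "cluster_assignment",
    "ClassicalMDS",
    "embed_mds",
    "AuSupport",
    "au_bootstrap",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 2) for i in range(10))
STRINGENT_AU_THRESHOLD = 0.9685


def _as_matrix(d) -> tuple[list[str], np.ndarray]:
    if isinstance(d, DissimilarityMatrix):
        return list(d.sample_ids), d.values
    arr = np.asarray(d, dtype=float)
    return [str(i) for i in range(arr.shape[0])], arr


@dataclass
class ClusterTree:
    """Agglomerative merge history over named leaves."""

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, k: int) -> pd.Series:
        """Cut into exactly k clusters; labels are 1..k."""
        labels = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        if len(set(labels)) != k:
            raise ValueError(f"cannot cut this tree into exactly {k} clusters")
        return pd.Series(labels, index=self.leaf_ids, name="cluster")

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.leaf_ids[i] for i in order]

    def clades(self) -> dict[frozenset[str], float]:
        """Leaf set and merge height of every internal node (root included)."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        out: dict[frozenset[str], float] = {}

        def walk(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([self.leaf_ids[node.id]])
            leaves = walk(node.left) | walk(node.right)
            out[leaves] = float(node.dist)
            return leaves

        walk(tree)
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0) if not node.is_leaf() else parent_dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{parent_dist - 0.0:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = walk(tree, tree.dist)
        # strip the root's zero-length branch
        return body.rsplit(":", 1)[0] + ";"


def hierarchical_cluster(d, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a symmetric dissimilarity matrix."""
    ids, mat = _as_matrix(d)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.any(mat < 0):
        raise ValueError("dissimilarities must be non-negative")
    condensed = squareform(mat, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(Z, ids, linkage)


@dataclass
class KSelection:
    ks: list[int]
    elbow_w: list[float]
    silhouette: list[float]
    recommended_k: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "W": self.elbow_w, "mean_silhouette": self.silhouette}
        ).set_index("k")


def _within_dispersion(mat: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = mat[np.ix_(idx, idx)]
        w += (sub**2).sum() / 2.0 / len(idx)
    return w


def choose_k(tree: ClusterTree, d, k_range=None) -> KSelection:
    """Elbow and silhouette curves over tree cuts; the silhouette argmax is
    the recommendation (the elbow curve is advisory).  Abstains (None) when
    all samples are mutually identical."""
    ids, mat = _as_matrix(d)
    n = len(ids)
    if k_range is None:
        k_range = range(2, min(n - 1, 10) + 1)
    if np.allclose(mat, 0.0):
        warnings.warn("silhouette undefined (identical samples); no k recommended",
                      stacklevel=2)
        return KSelection([], [], [], None)
    ks, ws, sils = [], [], []
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        try:
            labels = tree.cut(k).to_numpy()
        except ValueError:  # tied merge heights can make exact cuts infeasible
            continue
        ks.append(k)
        ws.append(_within_dispersion(mat, labels))
        sils.append(float(silhouette_score(mat, labels, metric="precomputed")))
    if not ks:
        warnings.warn("empty feasible k range; no k recommended", stacklevel=2)
        return KSelection(ks, ws, sils, None)
    return KSelection(ks, ws, sils, ks[int(np.nanargmax(sils))])


def cluster_assignment(tree: ClusterTree, d, k: int) -> pd.DataFrame:
    """Sample → cluster table at k clusters with per-sample silhouettes
    (silhouette of a singleton cluster is 0)."""
    ids, mat = _as_matrix(d)
    labels = tree.cut(k)
    if np.allclose(mat, 0.0):
        sil = np.zeros(len(ids))
    else:
        sil = silhouette_samples(mat, labels.to_numpy(), metric="precomputed")
    return pd.DataFrame(
        {"cluster": labels.to_numpy(), "silhouette": sil}, index=ids
    ).rename_axis("sample_id")


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-D**2 / 2``, eigendecomposes, and keeps the top positive
    eigenvalues up to ``n_components``.  For genuinely Euclidean input the
    embedding reproduces the distances exactly.

    Attributes
    ----------
    embedding_ : (n, k) coordinates.
    eigenvalues_ : all eigenvalues, descending.
    explained_ : fraction of the positive-eigenvalue mass kept.
    n_negative_eigenvalues_ : count of (truncated) negative eigenvalues.
    """

    def __init__(self, n_components: int = 2) -> None:
        self.n_components = n_components

    def fit(self, D, y=None):
        _, mat = _as_matrix(D)
        n = mat.shape[0]
        if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
            raise ValueError("distance matrix must be square and symmetric")
        dims = self.n_components
        if dims > n - 1:
            warnings.warn(f"n_components clipped from {dims} to {n - 1}", stacklevel=2)
            dims = max(n - 1, 1)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (mat**2) @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = max(n, 1) * np.finfo(float).eps * max(abs(vals[0]), 1.0)
        positive = np.flatnonzero(vals > tol)
        keep = positive[:dims]
        coords = vecs[:, keep] * np.sqrt(vals[keep])
        if coords.shape[1] == 0:
            coords = np.zeros((n, 1))
        self.eigenvalues_ = vals
        self.n_negative_eigenvalues_ = int((vals < -tol).sum())
        pos_mass = vals[positive].sum()
        self.explained_ = float(vals[keep].sum() / pos_mass) if pos_mass > 0 else 1.0
        self.embedding_ = coords
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    def transform(self, D):  # classical MDS has no out-of-sample map
        raise NotImplementedError("ClassicalMDS supports fit_transform only")


def embed_mds(d, dims: int = 2):
    """Thin wrapper over :class:`ClassicalMDS`; returns (coordinates, model)."""
    model = ClassicalMDS(n_components=dims)
    return model.fit_transform(d), model


# ---------------------------------------------------------------------------
# multiscale bootstrap AU support
# ---------------------------------------------------------------------------


@dataclass
class AuSupport:
    """Per-clade approximately-unbiased support values.

    ``table`` has one row per internal clade of the reference tree: its leaf
    ids, AU value, plain bootstrap probability at scale 1.0 and a flag for
    degenerate fits ("never_observed", "degenerate" or "").
    """

    table: pd.DataFrame
    bp_per_scale: dict[frozenset[str], dict[float, float]]
    scales: tuple[float, ...]
    replicates: int
    seed: int
    tree: ClusterTree

    def au_for(self, leaves) -> float:
        key = frozenset(leaves)
        row = self.table[self.table["leaves"].map(frozenset) == key]
        if row.empty:
            raise KeyError(f"no clade with leaves {sorted(key)}")
        return float(row["au"].iloc[0])

    def supported(self, threshold: float = STRINGENT_AU_THRESHOLD) -> pd.DataFrame:
        return self.table[self.table["au"] >= threshold]


def _replicate_clades(coords: np.ndarray, idx: np.ndarray, linkage: str) -> set[frozenset[int]]:
    """Distinct-label clades of one bootstrap replicate tree."""
    labels = np.unique(idx)
    if len(labels) < 3:
        return {frozenset(labels.tolist())} if len(labels) == 2 else set()
    Z = hierarchy.linkage(pdist(coords[idx]), method=linkage)
    m = len(idx)
    sets: list[frozenset[int]] = [frozenset([int(idx[i])]) for i in range(m)]
    out: set[frozenset[int]] = set()
    for a, b, _, _ in Z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        if len(merged) >= 2:
            out.add(merged)
    return out


def au_bootstrap(
    coords: np.ndarray,
    linkage: str = "complete",
    scales: tuple[float, ...] = DEFAULT_SCALES,
    replicates: int = 1000,
    seed: int = 0,
    leaf_ids: list[str] | None = None,
) -> AuSupport:
    """Multiscale bootstrap AU support for complete-linkage clades of
    embedded coordinates.

    For every scale ``r`` the rows are resampled with replacement to size
    ``round(r * n)`` and reclustered; a clade of the reference tree is
    recovered by a replicate when its restriction to the replicate's distinct
    leaves appears as a clade of the replicate tree (restrictions with fewer
    than two leaves are vacuously consistent).  AU values come from the weighted
    least-squares fit of ``z(r) = v sqrt(r) + c / sqrt(r)`` to
    ``z_r = Phi^{-1}(1 - BP_r)`` over scales with ``0 < BP_r < 1``
    (weights ``B phi(z)^2 / (BP (1 - BP))``).  A clade recovered in all or no
    replicates at nearly every scale has too few informative points for the
    fit; its AU falls back to the plain proportion at the scale nearest 1.0
    and is flagged ``degenerate``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]

    ref_tree = ClusterTree(
        hierarchy.linkage(pdist(coords), method=linkage), list(leaf_ids), linkage
    )
    ref_clades = [
        fs for fs in ref_tree.clades() if 2 <= len(fs) <= n - 1
    ]
    ref_index_sets = [
        frozenset(leaf_ids.index(x) for x in fs) for fs in ref_clades
    ]

    rng = np.random.default_rng(seed)
    counts: dict[float, np.ndarray] = {}
    for r in scales:
        m = max(int(round(r * n)), 2)
        hits = np.zeros(len(ref_index_sets))
        for _ in range(replicates):
            idx = rng.integers(0, n, size=m)
            distinct = frozenset(np.unique(idx).tolist())
            clades = _replicate_clades(coords, idx, linkage)
            for ci, S in enumerate(ref_index_sets):
                restriction = S & distinct
                if len(restriction) < 2 or restriction in clades:
                    hits[ci] += 1
        counts[r] = hits / replicates

    rows = []
    bp_per_scale: dict[frozenset[str], dict[float, float]] = {}
    r_nearest_1 = min(scales, key=lambda r: abs(r - 1.0))
    for ci, (fs_labels, fs_idx) in enumerate(zip(ref_clades, ref_index_sets)):
        bps = {r: float(counts[r][ci]) for r in scales}
        bp_per_scale[fs_labels] = bps
        bp1 = bps[r_nearest_1]
        usable = [(r, bp) for r, bp in bps.items() if 0.0 < bp < 1.0]
        flag = ""
        if all(bp == 0.0 for bp in bps.values()):
            au = 0.0
            flag = "never_observed"
        elif len(usable) < 2:
            au = bp1
            flag = "degenerate"
        else:
            rs = np.array([r for r, _ in usable])
            bp = np.array([b for _, b in usable])
            z = norm.ppf(1.0 - bp)
            X = np.column_stack([np.sqrt(rs), 1.0 / np.sqrt(rs)])
            w = replicates * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
            try:
                WX = X * w[:, None]
                beta = np.linalg.solve(X.T @ WX, WX.T @ z)
                v, c = beta
                au = float(1.0 - norm.cdf(v - c))
            except np.linalg.LinAlgError:
                au = bp1
                flag = "degenerate"
        rows.append(
            {
                "leaves": tuple(sorted(fs_labels)),
                "size": len(fs_labels),
                "au": au,
                "bp": bp1,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows, columns=["leaves", "size", "au", "bp", "flag"])
    table = table.sort_values(["size", "leaves"]).reset_index(drop=True)
    return AuSupport(table, bp_per_scale, tuple(scales), replicates, seed, ref_tree)
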