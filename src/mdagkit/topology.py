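"""Per-sample m-DAG topological descriptors and a multivariate outlier screen.

Descriptors mirror the usual m-DAG summaries: network size (reactions,
enzymes, compounds, MBB counts), connectivity (weak components, largest
component, isolated MBBs), largest-component structure (diameter, average
path length, average node degree, edge density) and essential-node counts.
Diameter and average path length treat arcs as undirected (directed DAGs
leave most ordered pairs unreachable); average path length averages over
unordered reachable pairs.  Edge density keeps the directed convention
``arcs / (n (n - 1))``.

The outlier screen standardizes the descriptor matrix, projects it onto the
smallest principal subspace holding a target fraction of variance, evaluates
squared Mahalanobis distances against a chi-square law with that many degrees
of freedom, and applies Benjamini–Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .graphs import MDag, find_essential_mbbs

__all__ = [
    "TopologyReport",
    "summarize_topology",
    "topology_table",
    "MahalanobisOutlierScreen",
    "detect_multivariate_outliers",
]


@dataclass(frozen=True)
class TopologyReport:
    sample_id: str
    n_reactions: int
    n_enzymes: int
    n_compounds: int
    n_mbbs: int
    n_mbbs_multi: int
    n_mbbs_single: int
    n_components: int
    largest_component_size: int
    n_isolated_mbbs: int
    lc_n_nodes: int
    lc_diameter: float
    lc_avg_path_length: float
    lc_avg_degree: float
    lc_edge_density: float
    n_essential: int
    prop_essential: float
    diameter_defined: bool = True

    def __post_init__(self) -> None:
        assert self.n_mbbs == self.n_mbbs_single + self.n_mbbs_multi
        assert 0.0 <= self.prop_essential <= 1.0
        assert self.largest_component_size <= self.n_mbbs


def summarize_topology(mdag: MDag, rg: nx.DiGraph, universe) -> TopologyReport:
    """Compute the descriptor vector of one sample's m-DAG."""
    sample_id = mdag.sample_id or rg.graph.get("sample_id") or ""
    reaction_ids = sorted({rg.nodes[n]["reaction"] for n in rg.nodes})
    n_reactions = len(reaction_ids)
    n_enzymes = len(universe.enzymes_of(reaction_ids))
    n_compounds = len(universe.compounds_of(reaction_ids))

    n_mbbs = len(mdag)
    n_multi = sum(1 for m in mdag if m.size > 1)
    n_single = n_mbbs - n_multi

    g = mdag.graph
    if n_mbbs == 0:
        return TopologyReport(
            sample_id, n_reactions, n_enzymes, n_compounds, 0, 0, 0, 0, 0, 0,
            0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, diameter_defined=False,
        )

    und = g.to_undirected(as_view=True)
    components = sorted(nx.connected_components(und), key=len, reverse=True)
    largest = components[0]
    n_isolated = sum(1 for n in g.nodes if g.degree(n) == 0)

    lc_n = len(largest)
    lc_sub = g.subgraph(largest)
    lc_und = lc_sub.to_undirected(as_view=True)
    n_arcs = lc_sub.number_of_edges()
    if lc_n >= 2:
        diameter = float(nx.diameter(lc_und))
        # average over unordered reachable pairs; for a connected undirected
        # graph this equals networkx's ordered-pair average by symmetry
        apl = float(nx.average_shortest_path_length(lc_und))
        avg_degree = 2.0 * n_arcs / lc_n
        density = n_arcs / (lc_n * (lc_n - 1))
        defined = True
    else:
        diameter, apl, avg_degree, density = 0.0, 0.0, 0.0, 0.0
        defined = False

    essential = find_essential_mbbs(mdag)
    return TopologyReport(
        sample_id=sample_id,
        n_reactions=n_reactions,
        n_enzymes=n_enzymes,
        n_compounds=n_compounds,
        n_mbbs=n_mbbs,
        n_mbbs_multi=n_multi,
        n_mbbs_single=n_single,
        n_components=len(components),
        largest_component_size=lc_n,
        n_isolated_mbbs=n_isolated,
        lc_n_nodes=lc_n,
        lc_diameter=diameter,
        lc_avg_path_length=apl,
        lc_avg_degree=avg_degree,
        lc_edge_density=density,
        n_essential=len(essential),
        prop_essential=len(essential) / n_mbbs,
        diameter_defined=defined,
    )


def topology_table(reports: list[TopologyReport]) -> pd.DataFrame:
    """One TSV-ready row per sample, indexed by sample id."""
    df = pd.DataFrame([asdict(r) for r in reports])
    return df.set_index("sample_id")


class MahalanobisOutlierScreen(OutlierMixin, BaseEstimator):
    """PCA + chi-square Mahalanobis outlier screen with FDR correction.

    Parameters
    ----------
    variance_kept : fraction of total variance the principal subspace must
        reach (smallest such subspace is used), default 0.95.
    alpha : Benjamini–Hochberg adjusted-p threshold for flagging, 0.05.

    Attributes
    ----------
    n_components_ : dimension of the retained principal subspace.
    distances_ : squared Mahalanobis distance of each training sample.
    pvalues_, pvalues_adj_ : upper-tail chi-square p-values and their BH
        adjustment.
    flags_ : boolean array, True where adjusted p < alpha.
    """

    def __init__(self, variance_kept: float = 0.95, alpha: float = 0.05) -> None:
        self.variance_kept = variance_kept
        self.alpha = alpha

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x descriptors)")
        n = X.shape[0]
        std = X.std(axis=0, ddof=1) if n > 1 else np.zeros(X.shape[1])
        keep = std > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant descriptor column(s)",
                stacklevel=2,
            )
        Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
        if Xs.shape[1] == 0:
            self.n_components_ = 0
            self.distances_ = np.zeros(n)
            self.pvalues_ = np.ones(n)
            self.pvalues_adj_ = np.ones(n)
            self.flags_ = np.zeros(n, dtype=bool)
            return self

        pca = PCA(n_components=min(n - 1, Xs.shape[1]) or 1, svd_solver="full")
        scores = pca.fit_transform(Xs)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_kept - 1e-12) + 1)
        k = min(k, scores.shape[1])
        lam = pca.explained_variance_[:k]
        positive = lam > 1e-12
        if not positive.all():
            warnings.warn("near-singular covariance; dropping null directions",
                          stacklevel=2)
        scores = scores[:, :k][:, positive]
        lam = lam[positive]
        k = scores.shape[1]

        # principal axes are uncorrelated: Mahalanobis^2 = sum score^2 / eigenvalue
        self.n_components_ = k
        if k == 0:
            self.distances_ = np.zeros(n)
            self.pvalues_ = np.ones(n)
        else:
            self.distances_ = (scores**2 / lam).sum(axis=1)
            self.pvalues_ = stats.chi2.sf(self.distances_, df=k)
        self.pvalues_adj_ = multipletests(self.pvalues_, method="fdr_bh")[1]
        self.flags_ = self.pvalues_adj_ < self.alpha
        return self

    def fit_predict(self, X, y=None):
        """sklearn outlier convention: -1 for flagged samples, +1 otherwise."""
        self.fit(X)
        return np.where(self.flags_, -1, 1)

    def report(self, sample_ids=None) -> pd.DataFrame:
        check_is_fitted(self, "flags_")
        n = len(self.flags_)
        idx = list(sample_ids) if sample_ids is not None else list(range(n))
        return pd.DataFrame(
            {
                "sample_id": idx,
                "distance": self.distances_,
                "df": self.n_components_,
                "p": self.pvalues_,
                "p_adj": self.pvalues_adj_,
                "flagged": self.flags_,
            }
        ).set_index("sample_id")


def detect_multivariate_outliers(
    features: pd.DataFrame, variance_kept: float = 0.95, alpha: float = 0.05
) -> pd.DataFrame:
    """Thin wrapper over :class:`MahalanobisOutlierScreen` for a descriptor
    DataFrame; returns the per-sample report indexed like the input."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples for the outlier screen")
    screen = MahalanobisOutlierScreen(variance_kept=variance_kept, alpha=alpha)
    screen.fit(features.to_numpy(dtype=float))
    return screen.report(sample_ids=features.index)
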