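"""Sparse PLS-DA over MBB completeness features and pathway roll-up.

Features are built against the pan m-DAG of the cohort: for each pan MBB
``M`` and sample ``s``, the value is the fraction of ``M``'s oriented
reactions present in ``s`` (completeness, in [0, 1]).  A two-component
sparse PLS-DA with a fixed number of non-zero loadings per component
(``keep_x``, mixOmics-style hard top-k selection) is fitted per pairwise
group comparison; it is used descriptively — no classification performance
is estimated.  Variables whose absolute contribution reaches 95% of the
component maximum are retained as discriminant MBBs, the loading sign
assigning each to the group whose score centroid lies on the same side.
Selected MBBs are finally expanded to their member reactions and counted per
pathway annotation.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .graphs import MDag, base_reaction

__all__ = [
    "build_mbb_features",
    "SparsePLSDA",
    "fit_splsda",
    "select_discriminants",
    "pathway_rollup",
]


def build_mbb_features(
    sample_oriented_reactions: Mapping[str, set[str]], pan_mdag: MDag
) -> pd.DataFrame:
    """Samples × pan-MBB completeness matrix.

    ``value(s, M) = |members(M) ∩ oriented_reactions(s)| / |members(M)|``.
    Column order follows sorted MBB ids; row order follows sorted sample ids.
    """
    mbb_ids = sorted(pan_mdag.mbbs)
    members = [pan_mdag.mbbs[m].members for m in mbb_ids]
    sizes = np.array([len(m) for m in members], dtype=float)
    rows = {}
    for sid in sorted(sample_oriented_reactions):
        labels = set(sample_oriented_reactions[sid])
        if not labels:
            warnings.warn(f"sample {sid!r} has an empty reaction set", stacklevel=2)
        rows[sid] = [len(m & labels) for m in members] / sizes
    return pd.DataFrame.from_dict(rows, orient="index", columns=mbb_ids)


class SparsePLSDA(TransformerMixin, BaseEstimator):
    """Sparse partial least squares discriminant analysis.

    Per component the loading vector starts from the dominant singular
    direction of the cross-covariance ``X^T Y`` (X column-standardized, Y
    centered one-hot), then alternates hard top-``keep_x[c]`` selection,
    renormalization and cross-covariance updates to convergence; X and Y are
    deflated by regression on the component scores.  With ``keep_x[c]``
    covering all features the sparse step is inactive and the component is
    the exact dominant singular direction (dense PLS-DA).

    Parameters
    ----------
    n_components : number of latent components (default 2).
    keep_x : non-zero loadings per component, e.g. ``(50, 30)``; values are
        clipped to the number of usable features with a warning.
    tol, max_iter : inner-loop convergence control.
    random_state : used only to break exact ties at the selection boundary.

    Attributes
    ----------
    classes_, x_loadings_ (p × ncomp, unit-norm, exactly ``keep_x[c]``
    non-zeros), x_scores_ (n × ncomp), kept_ (list of kept-feature index
    arrays), feature_names_in_, dropped_features_.
    """

    def __init__(
        self,
        n_components: int = 2,
        keep_x: tuple[int, ...] = (50, 30),
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int | None = 0,
    ) -> None:
        self.n_components = n_components
        self.keep_x = keep_x
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _dominant_pair(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        return U[:, 0], Vt[0]

    def _sparsify(self, u: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
        p = u.shape[0]
        if k >= p:
            nrm = np.linalg.norm(u)
            return u / nrm if nrm > 0 else u
        a = np.abs(u)
        cutoff = np.partition(a, p - k)[p - k]
        boundary = np.isclose(a, cutoff)
        if boundary.sum() > 1 and (a >= cutoff).sum() > k:
            # exact tie at the selection boundary: seeded infinitesimal jitter
            a = a + rng.uniform(0, 1e-12, size=p) * boundary
            cutoff = np.partition(a, p - k)[p - k]
        out = np.where(a >= cutoff, u, 0.0)
        nrm = np.linalg.norm(out)
        return out / nrm if nrm > 0 else out

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 groups")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("every group needs at least 2 samples")
        if len(self.keep_x) != self.n_components:
            raise ValueError("keep_x length must equal n_components")

        names = (
            np.asarray(X_df.columns)
            if X_df is not None
            else np.array([f"x{i}" for i in range(X.shape[1])])
        )
        std = X.std(axis=0, ddof=1)
        usable = std > 0
        if not usable.all():
            warnings.warn(
                f"dropping {int((~usable).sum())} zero-variance feature(s)",
                stacklevel=2,
            )
        self.dropped_features_ = names[~usable]
        names = names[usable]
        Xw = (X[:, usable] - X[:, usable].mean(axis=0)) / std[usable]
        n, p = Xw.shape
        Y = np.eye(len(classes))[y_idx]
        Y = Y - Y.mean(axis=0)

        rng = np.random.default_rng(self.random_state)
        loadings = np.zeros((p, self.n_components))
        scores = np.zeros((n, self.n_components))
        kept: list[np.ndarray] = []
        for c in range(self.n_components):
            k = int(self.keep_x[c])
            if k > p:
                warnings.warn(f"keep_x[{c}]={k} clipped to {p} features", stacklevel=2)
                k = p
            if k < 1:
                raise ValueError("keep_x entries must be >= 1")
            M = Xw.T @ Y
            u, v = self._dominant_pair(M)
            if k < p:
                for _ in range(self.max_iter):
                    u_new = self._sparsify(M @ v, k, rng)
                    v_new = M.T @ u_new
                    nrm = np.linalg.norm(v_new)
                    v_new = v_new / nrm if nrm > 0 else v_new
                    if np.linalg.norm(u_new - u) < self.tol:
                        u, v = u_new, v_new
                        break
                    u, v = u_new, v_new
            # deterministic sign: strongest loading positive
            pivot = int(np.argmax(np.abs(u)))
            if u[pivot] < 0:
                u = -u
            t = Xw @ u
            tt = float(t @ t)
            if tt > 0:
                Xw = Xw - np.outer(t, (t @ Xw) / tt)
                Y = Y - np.outer(t, (t @ Y) / tt)
            loadings[:, c] = u
            scores[:, c] = t
            kept.append(np.flatnonzero(u))

        self.classes_ = classes
        self.x_loadings_ = loadings
        self.x_scores_ = scores
        self.kept_ = kept
        self.feature_names_in_ = names
        self._y_idx = y_idx
        return self

    def transform(self, X=None):
        check_is_fitted(self, "x_scores_")
        if X is not None:
            raise NotImplementedError(
                "descriptive model: scores are available for the training data only"
            )
        return self.x_scores_

    def fit_transform(self, X, y=None):
        return self.fit(X, y).x_scores_

    def group_centroids(self) -> pd.DataFrame:
        """Mean score of each group on each component."""
        check_is_fitted(self, "x_scores_")
        rows = []
        for g, cls in enumerate(self.classes_):
            rows.append(self.x_scores_[self._y_idx == g].mean(axis=0))
        return pd.DataFrame(
            rows,
            index=list(self.classes_),
            columns=[f"comp{c + 1}" for c in range(self.n_components)],
        )


def fit_splsda(
    X, y, ncomp: int = 2, keepX: tuple[int, ...] = (50, 30), seed: int | None = 0
) -> SparsePLSDA:
    """Thin functional wrapper over :class:`SparsePLSDA`."""
    return SparsePLSDA(
        n_components=ncomp, keep_x=tuple(keepX), random_state=seed
    ).fit(X, y)


def select_discriminants(model: SparsePLSDA, threshold: float = 0.95) -> pd.DataFrame:
    """Retain, per component, the kept variables whose absolute contribution
    (loading weight on the standardized scale) reaches ``threshold`` times the
    component maximum; the loading sign assigns each variable to the group
    whose score centroid lies on the same side of the component."""
    check_is_fitted(model, "x_loadings_")
    centroids = model.group_centroids()
    rows = []
    for c in range(model.n_components):
        u = model.x_loadings_[:, c]
        nz = np.flatnonzero(u)
        if nz.size == 0:
            warnings.warn(f"component {c + 1} has no non-zero loadings", stacklevel=2)
            continue
        maxabs = np.abs(u[nz]).max()
        sel = nz[np.abs(u[nz]) >= threshold * maxabs - 1e-12]
        cent = centroids.iloc[:, c].to_numpy()
        for i in sel:
            sign = 1.0 if u[i] >= 0 else -1.0
            group = model.classes_[int(np.argmax(sign * cent))]
            rows.append(
                {
                    "component": c + 1,
                    "feature": model.feature_names_in_[i],
                    "contribution": float(u[i]),
                    "group": group,
                }
            )
    return pd.DataFrame(rows, columns=["component", "feature", "contribution", "group"])


def pathway_rollup(
    selected: pd.DataFrame, mbb_members: Mapping[str, frozenset], universe
) -> pd.DataFrame:
    """Count distinct reactions per pathway on each side of a comparison.

    Selected MBB features are expanded to member reactions (orientation
    collapsed), each distinct reaction counting once per pathway it belongs
    to; reactions without annotation land in ``unannotated``.
    """
    group_cols = [c for c in ("comparison", "group") if c in selected.columns]
    rows = []
    for keys, part in (
        selected.groupby(group_cols, sort=True) if group_cols else [((), selected)]
    ):
        if not isinstance(keys, tuple):
            keys = (keys,)
        reactions: set[str] = set()
        for feat in part["feature"]:
            reactions |= {base_reaction(lab) for lab in mbb_members[feat]}
        counts: dict[str, set[str]] = {}
        for rid in reactions:
            pws = universe.pathways_of(rid) or frozenset(["unannotated"])
            for pw in pws:
                counts.setdefault(pw, set()).add(rid)
        for pw in counts:
            rows.append(
                dict(
                    zip(group_cols, keys),
                    pathway=pw,
                    pathway_name=universe.pathway_names.get(pw, ""),
                    n_reactions=len(counts[pw]),
                )
            )
    df = pd.DataFrame(
        rows, columns=[*group_cols, "pathway", "pathway_name", "n_reactions"]
    )
    return df.sort_values(
        [*group_cols, "n_reactions", "pathway"],
        ascending=[*(True,) * len(group_cols), False, True],
    ).reset_index(drop=True)
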