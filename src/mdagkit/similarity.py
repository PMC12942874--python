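"""Two-step Munkres (maximum-weight bipartite matching) similarity of m-DAGs.

Step 1 scores a pair of MBBs: build the complete bipartite graph between
their member reactions, weight edges with a reaction similarity score,
solve the maximum-weight matching and divide the matched weight by the size
of the larger MBB.  Step 2 repeats the construction one level up, over the
MBBs of two m-DAGs with Step-1 similarities as weights, normalizing by the
MBB count of the larger m-DAG.  The similarity is turned into the Munkres
dissimilarity ``d = 1 - sim**2`` (a plain ``1 - sim`` variant is available).

The default reaction score is the identity on oriented-reaction labels
(1 iff same reaction id and orientation).  Under the identity score the
Step-1 matching weight equals the intersection size, so a fast closed-form
path is used for whole-matrix computation; the matching route remains the
reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .graphs import MBB, MDag

__all__ = [
    "ReactionScore",
    "IdentityScore",
    "TableScore",
    "mbb_similarity",
    "mdag_similarity",
    "dissimilarity_matrix",
    "DissimilarityMatrix",
]


class ReactionScore:
    """Symmetric similarity score over oriented-reaction labels, in [0, 1],
    with score(x, x) = 1."""

    def score(self, a: str, b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def is_identity(self) -> bool:
        return False


class IdentityScore(ReactionScore):
    """1 iff the two oriented-reaction labels are equal, else 0."""

    def score(self, a: str, b: str) -> float:
        return 1.0 if a == b else 0.0

    @property
    def is_identity(self) -> bool:
        return True


class TableScore(ReactionScore):
    """Graded score from a symmetric lookup table ``(a, b) -> value``;
    missing pairs default to 0, the diagonal to 1."""

    def __init__(self, table: Mapping[tuple[str, str], float]) -> None:
        self.table: dict[tuple[str, str], float] = {}
        for (a, b), v in table.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"score for {(a, b)} outside [0, 1]: {v}")
            self.table[(a, b)] = v
            self.table[(b, a)] = v

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.table.get((a, b), 0.0)


def _max_weight_matching_value(weights: np.ndarray) -> float:
    """Value of the maximum-weight matching of a rectangular weight matrix
    (weights >= 0; solved as an assignment problem via cost negation)."""
    if weights.size == 0:
        return 0.0
    rows, cols = linear_sum_assignment(-weights)
    return float(weights[rows, cols].sum())


def mbb_similarity(mbb1: MBB, mbb2: MBB, score: ReactionScore | None = None) -> float:
    """Step-1 similarity between two MBBs: matched reaction-score weight
    divided by the size of the larger MBB."""
    if score is None:
        score = IdentityScore()
    a = sorted(mbb1.members)
    b = sorted(mbb2.members)
    if not a or not b:
        raise ValueError("MBBs must be non-empty")
    w = np.array([[score.score(x, y) for y in b] for x in a], dtype=float)
    return _max_weight_matching_value(w) / max(len(a), len(b))


def _identity_step1_matrix(m1: MDag, m2: MDag) -> np.ndarray:
    """All Step-1 similarities between two m-DAGs under the identity score:
    pairwise intersection sizes over the larger MBB size, computed by a
    single pass over shared member labels."""
    ids1 = list(m1.mbbs)
    ids2 = list(m2.mbbs)
    pos1 = {mid: i for i, mid in enumerate(ids1)}
    pos2 = {mid: j for j, mid in enumerate(ids2)}
    counts = np.zeros((len(ids1), len(ids2)))
    lab1 = m1.member_to_mbb()
    lab2 = m2.member_to_mbb()
    for lab, mid1 in lab1.items():
        mid2 = lab2.get(lab)
        if mid2 is not None:
            counts[pos1[mid1], pos2[mid2]] += 1.0
    sizes1 = np.array([m1.mbbs[i].size for i in ids1], dtype=float)
    sizes2 = np.array([m2.mbbs[j].size for j in ids2], dtype=float)
    return counts / np.maximum.outer(sizes1, sizes2)


def mdag_similarity(m1: MDag, m2: MDag, score: ReactionScore | None = None) -> float:
    """Step-2 similarity between two m-DAGs: maximum-weight matching over the
    Step-1 MBB similarity matrix, divided by the MBB count of the larger
    m-DAG.  Empty m-DAGs: sim = 1 against empty, 0 against non-empty."""
    if score is None:
        score = IdentityScore()
    n1, n2 = len(m1), len(m2)
    if n1 == 0 and n2 == 0:
        return 1.0
    if n1 == 0 or n2 == 0:
        return 0.0
    if score.is_identity:
        w = _identity_step1_matrix(m1, m2)
    else:
        mbbs1 = list(m1.mbbs.values())
        mbbs2 = list(m2.mbbs.values())
        w = np.array(
            [[mbb_similarity(a, b, score) for b in mbbs2] for a in mbbs1]
        )
    return _max_weight_matching_value(w) / max(n1, n2)


DISSIMILARITY_TRANSFORMS = ("one_minus_sim_squared", "one_minus_sim")


def _apply_transform(sim: np.ndarray, transform: str) -> np.ndarray:
    if transform == "one_minus_sim_squared":
        return 1.0 - sim**2
    if transform == "one_minus_sim":
        return 1.0 - sim
    raise ValueError(f"unknown dissimilarity transform {transform!r}")


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise Munkres dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    similarities: np.ndarray | None = None
    transform: str = "one_minus_sim_squared"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.clip(self.values, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, si in enumerate(self.sample_ids):
            for j in range(i + 1, len(self.sample_ids)):
                rows.append(
                    {
                        "i": si,
                        "j": self.sample_ids[j],
                        "similarity": (
                            float(self.similarities[i, j])
                            if self.similarities is not None
                            else np.nan
                        ),
                        "dissimilarity": float(self.values[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["i", "j", "similarity", "dissimilarity"])

    def subset(self, keep: Sequence[str]) -> "DissimilarityMatrix":
        keep = [s for s in self.sample_ids if s in set(keep)]
        idx = [self.sample_ids.index(s) for s in keep]
        return DissimilarityMatrix(
            keep,
            self.values[np.ix_(idx, idx)],
            None if self.similarities is None else self.similarities[np.ix_(idx, idx)],
            self.transform,
        )

    def median_per_sample(self) -> pd.Series:
        """Median dissimilarity of each sample to all others — the reported
        ranking behind the extreme-dissimilarity screen."""
        n = len(self)
        med = np.array(
            [np.median(np.delete(self.values[i], i)) for i in range(n)]
        )
        return pd.Series(med, index=self.sample_ids).sort_values(ascending=False)

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t")
        return path


def dissimilarity_matrix(
    mdags: Mapping[str, MDag] | Sequence[tuple[str, MDag]],
    score: ReactionScore | None = None,
    transform: str = "one_minus_sim_squared",
) -> DissimilarityMatrix:
    """Pairwise Munkres dissimilarities over a cohort of m-DAGs.

    Input order is preserved; duplicate sample ids are rejected.
    """
    items = list(mdags.items()) if isinstance(mdags, Mapping) else list(mdags)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 m-DAGs")
    graphs = [m for _, m in items]
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = mdag_similarity(graphs[i], graphs[j], score)
    d = _apply_transform(sim, transform)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids, d, similarities=sim, transform=transform)
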