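"""Core and pan metabolism of sample groups.

The core reaction set of a group is the intersection of its members'
reaction sets, the pan the union.  Core and pan reaction graphs and m-DAGs
are rebuilt from those sets with the same arc policy as the per-sample
graphs, and summarized with the usual counts (reactions, enzymes, compounds,
MBB counts, essential MBBs and their proportion).  Each sample can also be
scored against its group's core/pan m-DAG with the two-step Munkres
similarity.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd

from .graphs import build_reaction_graph, condense_to_mdag
from .similarity import ReactionScore, mdag_similarity
from .topology import summarize_topology

__all__ = [
    "core_reactions",
    "pan_reactions",
    "group_mdag_summary",
    "essential_proportion",
]


def core_reactions(samples: Iterable[set[str]]) -> set[str]:
    """Intersection of the reaction sets of a group of samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("core of an empty sample list is undefined")
    out = set(samples[0])
    for s in samples[1:]:
        out &= set(s)
    return out


def pan_reactions(samples: Iterable[set[str]]) -> set[str]:
    """Union of the reaction sets of a group of samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("pan of an empty sample list is undefined")
    out: set[str] = set()
    for s in samples:
        out |= set(s)
    return out


def essential_proportion(n_essential: int, n_mbbs: int) -> float:
    """Proportion of essential MBBs, as reported in core/pan summaries
    (rounded to 4 decimals)."""
    if n_mbbs <= 0:
        return 0.0
    return round(n_essential / n_mbbs, 4)


SUMMARY_COLUMNS = [
    "group",
    "kind",
    "n_samples",
    "n_reactions",
    "n_enzymes",
    "n_compounds",
    "n_mbbs",
    "n_mbbs_multi",
    "n_mbbs_single",
    "n_essential",
    "prop_essential",
]


def group_mdag_summary(
    universe,
    groups: Mapping[str, Mapping[str, set[str]]],
    policy: str = "strict",
    score: ReactionScore | None = None,
    sample_similarity: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Core/pan m-DAG summary rows per group.

    Parameters
    ----------
    groups : ``group id -> {sample id -> reaction set}``; groups may overlap.
    sample_similarity : also compute each member sample's Munkres similarity
        to its group's core and pan m-DAGs.

    Returns
    -------
    (summary, similarity, mdags) : summary rows per group × {core, pan};
    optional long-form per-sample similarities; and the built m-DAGs keyed by
    ``(group, "core"|"pan")``.
    """
    rows = []
    sim_rows = []
    mdags: dict[tuple[str, str], object] = {}
    for gid in sorted(groups):
        members = groups[gid]
        if not members:
            warnings.warn(f"group {gid!r} has no samples; skipped", stacklevel=2)
            continue
        sets = [set(s) for s in members.values()]
        for kind, reactions in (
            ("core", core_reactions(sets)),
            ("pan", pan_reactions(sets)),
        ):
            rg = build_reaction_graph(
                universe, reactions, policy=policy, sample_id=f"{gid}_{kind}"
            )
            mdag = condense_to_mdag(rg)
            mdags[(gid, kind)] = mdag
            rep = summarize_topology(mdag, rg, universe)
            rows.append(
                {
                    "group": gid,
                    "kind": kind,
                    "n_samples": len(members),
                    "n_reactions": rep.n_reactions,
                    "n_enzymes": rep.n_enzymes,
                    "n_compounds": rep.n_compounds,
                    "n_mbbs": rep.n_mbbs,
                    "n_mbbs_multi": rep.n_mbbs_multi,
                    "n_mbbs_single": rep.n_mbbs_single,
                    "n_essential": rep.n_essential,
                    "prop_essential": essential_proportion(rep.n_essential, rep.n_mbbs),
                }
            )
            if sample_similarity:
                for sid, rset in sorted(members.items()):
                    srg = build_reaction_graph(universe, rset, policy=policy, sample_id=sid)
                    smd = condense_to_mdag(srg)
                    sim_rows.append(
                        {
                            "group": gid,
                            "kind": kind,
                            "sample_id": sid,
                            "similarity": mdag_similarity(smd, mdag, score),
                        }
                    )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    similarity = (
        pd.DataFrame(sim_rows, columns=["group", "kind", "sample_id", "similarity"])
        if sample_similarity
        else None
    )
    return summary, similarity, mdags
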