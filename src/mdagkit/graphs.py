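"""Reaction graphs and their condensation into metabolic DAGs (m-DAGs).

A reaction graph (RG) is a directed graph whose nodes are oriented reactions:
one forward node per reaction plus one backward node per reversible reaction
(the backward node swaps substrate and product sets and carries a ``rev``
suffix on its label).  There is an arc from oriented reaction ``u`` to ``v``
iff at least one compound produced by ``u`` is consumed by ``v``.

Contracting each strongly connected component (SCC) of the RG to a single
node yields the m-DAG; its nodes are called metabolic building blocks (MBBs).
Condensation preserves the number of (weak) connected components.  An MBB
consisting of a single oriented reaction is *essential* when deleting it
increases the number of weak components of the m-DAG — i.e. exactly when it
is an articulation point of the undirected m-DAG.

Note on the arc rule: under the verbatim rule the forward and backward
orientations of any reversible reaction always form a 2-cycle (each consumes
what the other produces), so every reversible reaction contributes a
multi-reaction MBB on its own.  The default ``strict`` policy keeps that
consequence; ``no-self-pair`` suppresses arcs between the two orientations of
one reaction for sensitivity analysis.  Self-arcs (a reaction producing a
compound it also consumes) are never created.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "REV_SUFFIX",
    "MBB",
    "MDag",
    "oriented_labels",
    "build_reaction_graph",
    "condense_to_mdag",
    "find_essential_mbbs",
    "export_graph_tsv",
    "export_mdag_tsv",
]

REV_SUFFIX = "rev"
ARC_POLICIES = ("strict", "no-self-pair")


def _rev_label(reaction_id: str) -> str:
    return reaction_id + REV_SUFFIX


def base_reaction(label: str) -> str:
    """Strip the orientation suffix from an oriented-reaction label."""
    return label[: -len(REV_SUFFIX)] if label.endswith(REV_SUFFIX) else label


def oriented_labels(universe, reaction_ids: Iterable[str]) -> set[str]:
    """Oriented-reaction node labels a reaction set expands to (forward node
    per reaction, plus a ``rev`` node per reversible reaction)."""
    out: set[str] = set()
    for rid in reaction_ids:
        rxn = universe.reactions[rid]
        out.add(rid)
        if rxn.reversible:
            out.add(_rev_label(rid))
    return out


def build_reaction_graph(
    universe,
    reactions: Iterable[str],
    policy: str = "strict",
    exclude_compounds: Iterable[str] = (),
    sample_id: str | None = None,
) -> nx.DiGraph:
    """Build the reaction graph for a reaction set.

    Parameters
    ----------
    universe : ReactionUniverse
    reactions : iterable of reaction ids present in the universe
    policy : ``"strict"`` (verbatim produced→consumed rule) or
        ``"no-self-pair"`` (omit arcs between the two orientations of the
        same reversible reaction).
    exclude_compounds : compounds removed from arc mediation (e.g. currency
        metabolites); none by default.
    """
    if policy not in ARC_POLICIES:
        raise ValueError(f"unknown arc policy {policy!r}")
    excluded = set(exclude_compounds)
    reactions = sorted(set(reactions))
    g = nx.DiGraph(sample_id=sample_id, universe_version=universe.version, policy=policy)

    # oriented nodes with their substrate/product sets
    produces: dict[str, frozenset[str]] = {}
    consumes: dict[str, frozenset[str]] = {}
    for rid in reactions:
        rxn = universe.reactions.get(rid)
        if rxn is None:
            raise KeyError(f"unknown reaction id {rid!r}")
        g.add_node(rid, reaction=rid, orientation="forward")
        produces[rid] = rxn.products
        consumes[rid] = rxn.substrates
        if rxn.reversible:
            lab = _rev_label(rid)
            g.add_node(lab, reaction=rid, orientation="backward")
            produces[lab] = rxn.substrates
            consumes[lab] = rxn.products

    # compound -> producers/consumers, then arcs producer -> consumer
    producers: dict[str, list[str]] = {}
    consumers: dict[str, list[str]] = {}
    for lab in sorted(g.nodes):
        for c in produces[lab]:
            if c not in excluded:
                producers.setdefault(c, []).append(lab)
        for c in consumes[lab]:
            if c not in excluded:
                consumers.setdefault(c, []).append(lab)
    for c in sorted(producers):
        for u in producers[c]:
            for v in consumers.get(c, ()):
                if u == v:
                    continue
                if policy == "no-self-pair" and g.nodes[u]["reaction"] == g.nodes[v]["reaction"]:
                    continue
                g.add_edge(u, v, compound=c)
    return g


def _mbb_id(members: Iterable[str]) -> str:
    """Stable content hash of an MBB's sorted member labels, shared across
    samples for identical reaction sets."""
    digest = hashlib.sha1("|".join(sorted(members)).encode()).hexdigest()[:12]
    return f"MBB_{digest}"


@dataclass(frozen=True)
class MBB:
    """One strongly connected component of a reaction graph."""

    id: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)

    @classmethod
    def from_members(cls, members: Iterable[str]) -> "MBB":
        members = frozenset(members)
        return cls(_mbb_id(members), members)


class MDag:
    """Condensation of a reaction graph: an acyclic digraph over MBBs."""

    def __init__(
        self,
        mbbs: Sequence[MBB],
        arcs: Iterable[tuple[str, str]] = (),
        sample_id: str | None = None,
    ) -> None:
        self.mbbs: dict[str, MBB] = {m.id: m for m in sorted(mbbs, key=lambda m: m.id)}
        if len(self.mbbs) != len(mbbs):
            raise ValueError("duplicate MBB ids (identical member sets) in one m-DAG")
        # MBBs are SCCs: they must partition the reaction-graph nodes
        if self.mbbs:
            total = sum(m.size for m in self.mbbs.values())
            distinct = len(set().union(*(m.members for m in self.mbbs.values())))
            if total != distinct:
                raise ValueError("MBB member sets overlap; not a valid condensation")
        self.graph = nx.DiGraph(sample_id=sample_id)
        self.graph.add_nodes_from(self.mbbs)
        for u, v in sorted(set(arcs)):
            if u == v:
                continue
            if u not in self.mbbs or v not in self.mbbs:
                raise KeyError(f"arc ({u}, {v}) references unknown MBB")
            self.graph.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("m-DAG arcs contain a cycle")
        self.sample_id = sample_id

    # -- container sugar ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.mbbs)

    def __iter__(self):
        return iter(self.mbbs.values())

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [m.members for m in self.mbbs.values()]

    @property
    def n_weak_components(self) -> int:
        if len(self.graph) == 0:
            return 0
        return nx.number_weakly_connected_components(self.graph)

    def member_to_mbb(self) -> dict[str, str]:
        return {lab: m.id for m in self.mbbs.values() for lab in m.members}


def condense_to_mdag(rg: nx.DiGraph) -> MDag:
    """Condense a reaction graph: each SCC becomes an MBB, condensation arcs
    are deduplicated, and the weak-component count is preserved."""
    cond = nx.condensation(rg)
    idx_to_mbb: dict[int, MBB] = {
        i: MBB.from_members(cond.nodes[i]["members"]) for i in cond.nodes
    }
    arcs = {(idx_to_mbb[u].id, idx_to_mbb[v].id) for u, v in cond.edges}
    return MDag(
        list(idx_to_mbb.values()), arcs, sample_id=rg.graph.get("sample_id")
    )


def find_essential_mbbs(mdag: MDag) -> set[str]:
    """MBB ids whose deletion increases the weak-component count.

    Only single-reaction MBBs qualify by definition.  Deleting a node
    increases the number of weak components exactly when it is an
    articulation point of the undirected m-DAG, which is what is computed
    here (linear time, vs. exhaustive deletion).
    """
    und = mdag.graph.to_undirected(as_view=True)
    articulation = set(nx.articulation_points(und))
    return {mid for mid in articulation if mdag.mbbs[mid].size == 1}


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_graph_tsv(rg: nx.DiGraph, prefix: str | Path) -> tuple[Path, Path]:
    """Write a 2-column edge list and a node-attribute table."""
    prefix = Path(prefix)
    edges = pd.DataFrame(sorted(rg.edges), columns=["source", "target"])
    nodes = pd.DataFrame(
        [
            {"label": n, "reaction": rg.nodes[n]["reaction"],
             "orientation": rg.nodes[n]["orientation"]}
            for n in sorted(rg.nodes)
        ],
        columns=["label", "reaction", "orientation"],
    )
    edge_path = prefix.with_suffix(".edges.tsv")
    node_path = prefix.with_suffix(".nodes.tsv")
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
    return edge_path, node_path


def export_mdag_tsv(
    mdag: MDag, prefix: str | Path, essential: set[str] | None = None
) -> tuple[Path, Path]:
    """Write the m-DAG arc list and the MBB membership table."""
    prefix = Path(prefix)
    if essential is None:
        essential = find_essential_mbbs(mdag)
    arcs = pd.DataFrame(sorted(mdag.graph.edges), columns=["source", "target"])
    nodes = pd.DataFrame(
        [
            {
                "mbb_id": m.id,
                "size": m.size,
                "essential": int(m.id in essential),
                "members": ",".join(sorted(m.members)),
            }
            for m in mdag
        ],
        columns=["mbb_id", "size", "essential", "members"],
    )
    arc_path = prefix.with_suffix(".arcs.tsv")
    node_path = prefix.with_suffix(".mbbs.tsv")
    arcs.to_csv(arc_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
    return arc_path, node_path


def export_graphml(graph_or_mdag, path: str | Path) -> Path:
    path = Path(path)
    g = graph_or_mdag.graph if isinstance(graph_or_mdag, MDag) else graph_or_mdag
    g = g.copy()
    if isinstance(graph_or_mdag, MDag):
        for mid, mbb in graph_or_mdag.mbbs.items():
            g.nodes[mid]["members"] = ",".join(sorted(mbb.members))
            g.nodes[mid]["size"] = mbb.size
    for key in list(g.graph):
        if g.graph[key] is None:
            del g.graph[key]
    nx.write_graphml(g, path)
    return path
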