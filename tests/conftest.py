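import numpy as np
import pytest

import mdagkit as mk
from mdagkit.synthetic import generate_cohort, generate_universe

F1_REACTIONS = ["R1", "R2", "R3", "R4"]


@pytest.fixture(scope="session")
def f1():
    return mk.fixture_universe("F1")


@pytest.fixture(scope="session")
def f2():
    return mk.fixture_universe("F2")


@pytest.fixture(scope="session")
def f1_rg(f1):
    return mk.build_reaction_graph(f1, F1_REACTIONS)


@pytest.fixture(scope="session")
def f1_mdag(f1_rg):
    return mk.condense_to_mdag(f1_rg)


@pytest.fixture(scope="session")
def f2_rg(f2):
    return mk.build_reaction_graph(f2, ["P1", "P2", "P3"])


@pytest.fixture(scope="session")
def f2_mdag(f2_rg):
    return mk.condense_to_mdag(f2_rg)


def random_digraph(rng: np.random.Generator, n_max: int = 12, p: float = 0.25):
    """Random labelled digraph as a networkx DiGraph (no self-loops)."""
    import networkx as nx

    n = int(rng.integers(1, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


@pytest.fixture(scope="session")
def synthetic_run():
    """Default synthetic cohort (3 groups x 10 individuals x 4 samples,
    seed 1) pushed through graphs, dissimilarity and clustering once."""
    synth = generate_universe(seed=1)
    cohort = generate_cohort(synth, seed=1)
    sample_reactions = {
        sid: set(mk.map_kos_to_reactions(synth.universe, sorted(kos)))
        for sid, kos in cohort.sample_kos().items()
    }
    mdags = {
        sid: mk.condense_to_mdag(
            mk.build_reaction_graph(synth.universe, rset, sample_id=sid)
        )
        for sid, rset in sample_reactions.items()
    }
    d = mk.dissimilarity_matrix(mdags)
    tree = mk.hierarchical_cluster(d)
    selection = mk.choose_k(tree, d)
    return {
        "synth": synth,
        "cohort": cohort,
        "sample_reactions": sample_reactions,
        "mdags": mdags,
        "dissimilarity": d,
        "tree": tree,
        "k_selection": selection,
    }


def random_mdag(rng: np.random.Generator, pool, max_mbbs: int = 6, max_size: int = 3):
    """Random valid m-DAG: member sets drawn as a partition of a subsample."""
    from mdagkit.graphs import MBB, MDag

    n_mbbs = int(rng.integers(1, max_mbbs + 1))
    sizes = rng.integers(1, max_size + 1, size=n_mbbs)
    labels = rng.choice(pool, size=int(sizes.sum()), replace=False)
    sets, start = [], 0
    for s in sizes:
        sets.append(frozenset(labels[start: start + s]))
        start += s
    return MDag([MBB.from_members(s) for s in sets])
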