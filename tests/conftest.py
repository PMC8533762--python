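import networkx as nx
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from melpath.pathways import PathwayGraph

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_graph(pid, nodes, edges, genes=None):
    """nodes: list of node ids; edges: (u, v, sign); genes defaults to one
    gene per node named '<node>g'."""
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(n, genes=tuple(genes[n]) if genes and n in genes else (f"{n}g",))
    for u, v, s in edges:
        g.add_edge(u, v, sign=s)
    return PathwayGraph(pid, g)


def random_dag(rng, n_nodes, p_edge=0.4, p_inhib=0.3):
    """Random signed DAG on an ordered node set; falls back to a chain when
    no edge is drawn. Isolated nodes are dropped."""
    nodes = [f"n{i}" for i in range(max(2, n_nodes))]
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < p_edge:
                edges.append((nodes[i], nodes[j], -1 if rng.random() < p_inhib else 1))
    if not edges:
        edges = [(a, b, 1) for a, b in zip(nodes, nodes[1:])]
    used = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    return make_graph("rand", [n for n in nodes if n in used], edges)


@pytest.fixture(scope="session")
def cohort_fixture():
    from melpath.cohort import melanoma_cohort_fixture

    return melanoma_cohort_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_groups(cohort_fixture):
    _, records = cohort_fixture
    return pd.Series({r.tumor_id: r.group for r in records})


@pytest.fixture
def chain3():
    return make_graph("chain", ["A", "B", "C"], [("A", "B", 1), ("B", "C", 1)])


@pytest.fixture
def diamond():
    return make_graph(
        "dia", ["A", "B", "C", "D"],
        [("A", "B", 1), ("A", "C", 1), ("B", "D", 1), ("C", "D", 1)],
    )
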