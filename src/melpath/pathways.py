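"""Signaling-pathway graphs, effector-circuit decomposition, and mechanistic
activity propagation.

A pathway is a directed acyclic graph with signed edges (activation /
inhibition); receptor nodes have in-degree 0 and effector nodes out-degree 0
(explicit ``role`` annotations override the degree inference). A *circuit*
is, for one effector, the sub-DAG of every receptor-to-effector path; its
activity summarises the signal reaching that effector.

Expression is first rank-rescaled into the open interval (0, 1) over the
whole matrix (rank / (N + 1), ties averaged). Node values are the mean of
their member genes' rescaled values, and signal propagates in topological
order: a receptor outputs its own value, and any other node outputs

    S(n) = v(n) * (1 - prod_a (1 - S(a))) * prod_i (1 - S(i))

over its activating parents ``a`` and inhibiting parents ``i``; the circuit
activity is the effector's ``S``. Activities are non-decreasing in any
activator-path value and non-increasing in any inhibitor value, and reduce
to a plain product of node values along a pure chain.

Cyclic topologies are rejected at parse time; keeping the model on DAGs
makes activities well-defined and bit-reproducible (a documented
limitation for feedback motifs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

EPS = 1e-12

ACTIVATION = "activation"
INHIBITION = "inhibition"
_SIGNS = {ACTIVATION: +1, INHIBITION: -1}


@dataclass
class PathwayGraph:
    pathway_id: str
    graph: nx.DiGraph  # node attr "genes": tuple[str]; edge attr "sign": +-1

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"pathway {self.pathway_id} contains a cycle: {cycle}")
        for n, data in self.graph.nodes(data=True):
            if not data.get("genes"):
                raise ValueError(f"node {n} in {self.pathway_id} has no genes")

    def _role_nodes(self, role: str, degree_fn) -> list[str]:
        explicit = [n for n, d in self.graph.nodes(data=True) if d.get("role") == role]
        if explicit:
            return sorted(explicit)
        return sorted(n for n, deg in degree_fn() if deg == 0)

    @property
    def receptors(self) -> list[str]:
        return self._role_nodes("receptor", self.graph.in_degree)

    @property
    def effectors(self) -> list[str]:
        return self._role_nodes("effector", self.graph.out_degree)

    @property
    def genes(self) -> set[str]:
        return {g for _, d in self.graph.nodes(data=True) for g in d["genes"]}


@dataclass
class Circuit:
    """All receptor-to-effector paths for one effector of one pathway."""

    pathway_id: str
    effector: str
    subgraph: nx.DiGraph

    @property
    def circuit_id(self) -> str:
        return f"{self.pathway_id}:{self.effector}"

    @property
    def genes(self) -> set[str]:
        return {g for _, d in self.subgraph.nodes(data=True) for g in d["genes"]}


@dataclass(frozen=True)
class RescaleConfig:
    per_gene: bool = False  # default: single ranking over the whole matrix


def parse_pathways(sif_path, node_gene_map_path) -> list[PathwayGraph]:
    """Build validated pathway graphs from a SIF edge list and a node map.

    SIF lines are ``source<TAB>relation<TAB>target`` with relation
    ``activation`` or ``inhibition``; the node map TSV has columns
    ``node_id``, ``gene``, ``pathway_id`` (one row per member gene) and an
    optional ``role`` column (receptor/effector) overriding degree
    inference.
    """
    nm = pd.read_csv(node_gene_map_path, sep="\t", dtype=str)
    required = {"node_id", "gene", "pathway_id"}
    if not required <= set(nm.columns):
        raise ValueError(f"node map must have columns {sorted(required)}")
    node_pathway: dict[str, str] = {}
    graphs: dict[str, nx.DiGraph] = {}
    for pid, sub in nm.groupby("pathway_id", sort=True):
        g = nx.DiGraph()
        for node_id, rows in sub.groupby("node_id", sort=True):
            attrs = {"genes": tuple(sorted(rows["gene"]))}
            if "role" in rows and rows["role"].notna().any():
                attrs["role"] = rows["role"].dropna().iloc[0]
            g.add_node(node_id, **attrs)
            node_pathway[node_id] = pid
        graphs[pid] = g

    with open(sif_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{sif_path}:{lineno}: expected 3 tab-separated fields")
            src, rel, dst = parts
            if rel not in _SIGNS:
                raise ValueError(f"{sif_path}:{lineno}: unknown relation {rel!r}")
            for n in (src, dst):
                if n not in node_pathway:
                    raise ValueError(f"{sif_path}:{lineno}: node {n!r} absent from node map")
            if node_pathway[src] != node_pathway[dst]:
                raise ValueError(f"{sif_path}:{lineno}: edge crosses pathways")
            graphs[node_pathway[src]].add_edge(src, dst, sign=_SIGNS[rel])

    return [PathwayGraph(pid, g) for pid, g in sorted(graphs.items())]


def decompose_circuits(g: PathwayGraph) -> list[Circuit]:
    """One circuit per effector: the induced sub-DAG of the effector and all
    of its ancestors reachable from a receptor. Effectors with no incoming
    receptor path are skipped with a warning; ordering is by effector id."""
    receptors = set(g.receptors)
    circuits = []
    for eff in g.effectors:
        nodes = nx.ancestors(g.graph, eff) | {eff}
        reachable = set()
        for r in receptors & nodes:
            reachable |= nx.descendants(g.graph, r) | {r}
        nodes &= reachable
        if eff not in nodes or len(nodes) == 1:  # isolated or receptor-less
            warnings.warn(
                f"effector {eff} of {g.pathway_id} unreachable from any receptor; skipped",
                stacklevel=2,
            )
            continue
        circuits.append(Circuit(g.pathway_id, eff, g.graph.subgraph(nodes).copy()))
    return circuits


def rank_rescale(x: pd.DataFrame, cfg: RescaleConfig = RescaleConfig()) -> pd.DataFrame:
    """Map expression onto (0, 1) by rank/(N+1) with average ties.

    By default all entries of the matrix are ranked together; ``per_gene``
    ranks each row separately. NA entries are an error.
    """
    vals = x.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains NA/non-finite entries")
    if cfg.per_gene:
        out = np.apply_along_axis(
            lambda row: rankdata(row, method="average") / (row.size + 1), 1, vals
        )
    else:
        out = (rankdata(vals, method="average") / (vals.size + 1)).reshape(vals.shape)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def node_value(genes, rescaled: pd.Series | pd.DataFrame):
    """Value of a (possibly multi-gene) node: arithmetic mean of members."""
    missing = [g for g in genes if g not in rescaled.index]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")
    sub = rescaled.loc[list(genes)]
    return sub.mean(axis=0) if isinstance(rescaled, pd.DataFrame) else float(sub.mean())


@dataclass
class _CompiledCircuit:
    """Topologically ordered evaluation plan for fast vectorised propagation."""

    circuit: Circuit
    order: list[str] = field(init=False)
    parents: dict[str, tuple[list[str], list[str]]] = field(init=False)

    def __post_init__(self) -> None:
        sg = self.circuit.subgraph
        self.order = list(nx.lexicographical_topological_sort(sg))
        self.parents = {
            n: (
                [u for u in sg.predecessors(n) if sg.edges[u, n]["sign"] > 0],
                [u for u in sg.predecessors(n) if sg.edges[u, n]["sign"] < 0],
            )
            for n in self.order
        }

    def evaluate(self, values: dict[str, np.ndarray]) -> np.ndarray:
        s: dict[str, np.ndarray] = {}
        for n in self.order:
            acts, inhs = self.parents[n]
            v = np.clip(values[n], EPS, 1 - EPS)
            if not acts and not inhs:
                s[n] = v
                continue
            out = v
            if acts:
                miss = np.ones_like(v)
                for a in acts:
                    miss = miss * (1 - s[a])
                out = out * (1 - miss)
            for i in inhs:
                out = out * (1 - s[i])
            s[n] = np.clip(out, EPS, 1 - EPS)
        return s[self.circuit.effector]


def propagate(c: Circuit, node_values: dict[str, float]) -> float:
    """Activity of one circuit for one sample's node values."""
    arrs = {n: np.asarray([float(node_values[n])]) for n in c.subgraph.nodes}
    return float(_CompiledCircuit(c).evaluate(arrs)[0])


@dataclass
class ActivityDataset:
    """Circuits x samples activity matrix with per-sample group labels."""

    activities: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        self.sample_groups = self.sample_groups.reindex(self.activities.columns)
        if self.sample_groups.isna().any():
            missing = list(self.sample_groups.index[self.sample_groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")


def activity_matrix(
    graphs: list[PathwayGraph],
    rescaled: pd.DataFrame,
    labels: pd.Series,
) -> ActivityDataset:
    """Propagate every circuit of every pathway over all sample columns."""
    circuits = [c for g in graphs for c in decompose_circuits(g)]
    if not circuits:
        raise ValueError("no circuits to evaluate")
    rows = {}
    for c in circuits:
        values = {
            n: node_value(c.subgraph.nodes[n]["genes"], rescaled).to_numpy(dtype=float)
            for n in c.subgraph.nodes
        }
        rows[c.circuit_id] = _CompiledCircuit(c).evaluate(values)
    acts = pd.DataFrame.from_dict(rows, orient="index", columns=rescaled.columns)
    return ActivityDataset(acts.sort_index(), labels)
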