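"""Synthetic inputs with known ground truth for the whole pipeline.

The real inputs — normal-skin expression, curated signaling topologies, and
text-mined hallmark scores — are emulated here with generators whose
statistical structure mirrors the study conditions:

* cohorts of 82 nevogenic + 37 CSD tumors with per-gene, per-group mutation
  probabilities defaulting to the published prevalence frequencies;
* log-normal normal-tissue expression with gene-specific means;
* small random signed DAG pathways with receptors, effectors and a tunable
  inhibition fraction, plus designed pathways for planting known effects;
* right-skewed (exponential) hallmark scores calibrated so that roughly 10%
  of scores exceed the 0.18 annotation cut.

Every generator is a pure function of (parameters, seed); `write_run_dir`
emits a complete plain-text run directory (cohort.tsv, expr.tsv,
pathways.sif, node_map.tsv, hallmarks.tsv, truth.json).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CSD, NEVOGENIC, GeneStatusMatrix, PatientRecord
from .pathways import ACTIVATION, INHIBITION, PathwayGraph, decompose_circuits
from .reference import CANONICAL_HALLMARKS, GENE_MUT_PROBS, N_CSD, N_NEVOGENIC

#: Exponential scale such that P(score > 0.18) = 0.1.
HALLMARK_SCALE = 0.18 / np.log(10.0)


@dataclass
class SyntheticScenario:
    seed: int = 0
    n_nevogenic: int = N_NEVOGENIC
    n_csd: int = N_CSD
    gene_mut_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GENE_MUT_PROBS)
    )
    n_pathways: int = 5
    nodes_per_pathway: int = 10
    edge_prob: float = 0.35
    inhibition_fraction: float = 0.25
    n_normal_samples: int = 30
    #: (gene, group, "inhibitor"/"activator"): wire this mutated gene onto an
    #: edge of the stated sign in a dedicated pathway so its knockdown has a
    #: known direction of effect.
    planted_effects: list[tuple[str, str, str]] = field(default_factory=list)
    #: log-scale expression means for named genes (others drawn at random).
    #: Planted genes default to a high mean (two SD above average) so their
    #: knockdown produces a large activity change.
    gene_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nevogenic < 2 or self.n_csd < 2:
            raise ValueError("group sizes must be >= 2")
        for g, (p1, p2) in self.gene_mut_probs.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValueError(f"probability outside [0,1] for {g}")


def gen_cohort(s: SyntheticScenario) -> tuple[GeneStatusMatrix, list[PatientRecord]]:
    """Bernoulli mutation draws per gene with group-specific probabilities;
    nevus counts and elastosis grades consistent with the group rules."""
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 1]))
    genes = list(s.gene_mut_probs)
    rows, records = [], []
    for gidx, (gname, n, prefix) in enumerate(
        ((NEVOGENIC, s.n_nevogenic, "SNV"), (CSD, s.n_csd, "SCS"))
    ):
        probs = np.array([s.gene_mut_probs[g][gidx] for g in genes])
        draws = (rng.random((n, len(genes))) < probs).astype(float)
        for i in range(n):
            tid = f"{prefix}{i + 1:03d}"
            rows.append(dict(zip(genes, draws[i])))
            if gname == NEVOGENIC:
                nevi, grade = int(rng.integers(51, 151)), "0"
            else:
                nevi = int(rng.integers(0, 20))
                grade = str(rng.choice(["2-", "2", "2+", "3-", "3", "3+"]))
            records.append(PatientRecord(tid, nevi, grade, gname))
    df = pd.DataFrame(rows, index=[r.tumor_id for r in records], dtype=float)
    return GeneStatusMatrix(df), records


def gen_expression(
    genes, n_samples: int, seed: int = 0, gene_means: dict[str, float] | None = None
) -> pd.DataFrame:
    """Log-normal expression (genes x samples) with gene-specific means;
    ``gene_means`` pins the log-scale mean of named genes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genes = list(genes)
    mu = rng.normal(2.0, 1.0, size=len(genes))  # log-scale gene means
    for i, g in enumerate(genes):
        if gene_means and g in gene_means:
            mu[i] = gene_means[g]
    vals = np.exp(mu[:, None] + rng.normal(0.0, 0.5, size=(len(genes), n_samples)))
    cols = [f"GTEX{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(vals, index=genes, columns=cols)


def _random_dag(
    rng: np.random.Generator, pid: str, n_nodes: int, edge_prob: float,
    inhibition_fraction: float,
) -> PathwayGraph:
    g = nx.DiGraph()
    names = [f"{pid}_N{i + 1}" for i in range(n_nodes)]
    for i, n in enumerate(names):
        g.add_node(n, genes=(f"{pid}G{i + 1}",))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                sign = -1 if rng.random() < inhibition_fraction else +1
                g.add_edge(names[i], names[j], sign=sign)
    # guarantee connectivity of interior nodes so receptors/effectors exist
    for j in range(1, n_nodes):
        if g.in_degree(names[j]) == 0 and g.out_degree(names[j]) > 0:
            g.add_edge(names[0], names[j], sign=+1)
    isolated = [n for n in names if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    if g.number_of_nodes() == 0:  # degenerate draw: fall back to a chain
        for i, n in enumerate(names):
            g.add_node(n, genes=(f"{pid}G{i + 1}",))
            if i:
                g.add_edge(names[i - 1], n, sign=+1)
    return PathwayGraph(pid, g)


def planted_pathway(pid: str, gene: str, sign: str) -> PathwayGraph:
    """A designed 4-node circuit whose ``gene`` sits on an edge of known sign.

    Receptor R -> effector E carries the main signal; ``gene`` occupies node
    M feeding E through an activating or inhibiting edge, so knocking the
    gene down has a known direction of effect on the circuit activity.
    """
    g = nx.DiGraph()
    g.add_node(f"{pid}_R", genes=(f"{pid}G_R",))
    g.add_node(f"{pid}_A", genes=(f"{pid}G_A",))
    g.add_node(f"{pid}_M", genes=(gene,))
    g.add_node(f"{pid}_E", genes=(f"{pid}G_E",))
    g.add_edge(f"{pid}_R", f"{pid}_A", sign=+1)
    g.add_edge(f"{pid}_A", f"{pid}_E", sign=+1)
    g.add_edge(f"{pid}_R", f"{pid}_M", sign=+1)
    g.add_edge(
        f"{pid}_M", f"{pid}_E", sign=-1 if sign == "inhibitor" else +1
    )
    return PathwayGraph(pid, g)


def scenario_gene_means(s: SyntheticScenario) -> dict[str, float]:
    """Effective per-gene expression means.

    A planted effect is, by definition, a constitutively active circuit held
    in check by a highly expressed gene on the signed edge: the planted gene
    and the designed circuit's scaffold genes default to a log-mean of 4.0
    (two SD above the population average), so the knockdown produces a large
    activity change. Explicit ``gene_means`` entries override.
    """
    means: dict[str, float] = {}
    for k, (gene, _group, _sign) in enumerate(s.planted_effects):
        pid = f"PLANT{k + 1}"
        means[gene] = 4.0
        for suffix in ("R", "A", "E"):
            means[f"{pid}G_{suffix}"] = 4.0
    means.update(s.gene_means)
    return means


def gen_pathways(s: SyntheticScenario) -> list[PathwayGraph]:
    """Random DAG pathways plus one designed pathway per planted effect."""
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 3]))
    graphs = [
        _random_dag(rng, f"P{i + 1:02d}", s.nodes_per_pathway, s.edge_prob,
                    s.inhibition_fraction)
        for i in range(s.n_pathways)
    ]
    for k, (gene, _group, sign) in enumerate(s.planted_effects):
        graphs.append(planted_pathway(f"PLANT{k + 1}", gene, sign))
    return graphs


def gen_hallmark_scores(
    circuit_ids, hallmarks=CANONICAL_HALLMARKS, seed: int = 0,
    scale: float = HALLMARK_SCALE,
) -> pd.DataFrame:
    """Exponential scores per (circuit, hallmark): heavy right tail with
    about 10% of rows above the 0.18 annotation cut at the default scale."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    rows = [
        {"circuit_id": cid, "hallmark": h, "score": float(rng.exponential(scale))}
        for cid in circuit_ids
        for h in hallmarks
    ]
    return pd.DataFrame(rows, columns=["circuit_id", "hallmark", "score"])


def write_sif(graphs: list[PathwayGraph], sif_path, node_map_path) -> None:
    with open(sif_path, "w") as fh:
        for g in graphs:
            for u, v, d in g.graph.edges(data=True):
                rel = ACTIVATION if d["sign"] > 0 else INHIBITION
                fh.write(f"{u}\t{rel}\t{v}\n")
    rows = [
        {"node_id": n, "gene": gene, "pathway_id": g.pathway_id}
        for g in graphs
        for n, d in g.graph.nodes(data=True)
        for gene in d["genes"]
    ]
    pd.DataFrame(rows).to_csv(node_map_path, sep="\t", index=False)


def write_run_dir(path, s: SyntheticScenario) -> Path:
    """Emit a complete run directory for the scenario; returns the path."""
    from .cohort import write_cohort_tsv

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    matrix, records = gen_cohort(s)
    write_cohort_tsv(out / "cohort.tsv", matrix, records)
    graphs = gen_pathways(s)
    write_sif(graphs, out / "pathways.sif", out / "node_map.tsv")
    circuits = [c.circuit_id for g in graphs for c in decompose_circuits(g)]
    genes = sorted({g for gr in graphs for g in gr.genes} | set(matrix.genes) - {"TERTp"})
    expr = gen_expression(genes, s.n_normal_samples, seed=s.seed,
                          gene_means=scenario_gene_means(s))
    expr.to_csv(out / "expr.tsv", sep="\t", index_label="gene")
    gen_hallmark_scores(circuits, seed=s.seed).to_csv(
        out / "hallmarks.tsv", sep="\t", index=False
    )
    truth = {
        "seed": s.seed,
        "circuits": circuits,
        "planted_effects": [list(e) for e in s.planted_effects],
        "n_nevogenic": s.n_nevogenic,
        "n_csd": s.n_csd,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
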