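"""Pathway parsing, effector-circuit decomposition against a path-enumeration
oracle, rank rescaling, and propagation properties."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_graph, random_dag
from melpath.pathways import (
    PathwayGraph,
    RescaleConfig,
    activity_matrix,
    decompose_circuits,
    node_value,
    parse_pathways,
    propagate,
    rank_rescale,
)


def oracle_circuit_subgraph(g: PathwayGraph, effector: str) -> tuple[set, set]:
    """Union of all simple receptor->effector paths, by direct enumeration."""
    nodes, edges = set(), set()
    for r in g.receptors:
        for path in nx.all_simple_paths(g.graph, r, effector):
            nodes.update(path)
            edges.update(zip(path, path[1:]))
        if r == effector:
            nodes.add(r)
    return nodes, edges


def write_pathway_files(tmp_path, lines, node_rows):
    sif = tmp_path / "p.sif"
    sif.write_text("".join(f"{a}\t{r}\t{b}\n" for a, r, b in lines))
    nm = tmp_path / "nm.tsv"
    nm.write_text(
        "node_id\tgene\tpathway_id\n"
        + "".join(f"{n}\t{g}\t{p}\n" for n, g, p in node_rows)
    )
    return sif, nm


class TestParse:
    def test_three_node_chain_single_circuit(self, tmp_path):
        sif, nm = write_pathway_files(
            tmp_path,
            [("A", "activation", "B"), ("B", "activation", "C")],
            [("A", "gA", "P1"), ("B", "gB", "P1"), ("C", "gC", "P1")],
        )
        (g,) = parse_pathways(sif, nm)
        assert g.receptors == ["A"] and g.effectors == ["C"]
        circuits = decompose_circuits(g)
        assert len(circuits) == 1 and circuits[0].circuit_id == "P1:C"

    def test_two_receptors_converging(self, tmp_path):
        sif, nm = write_pathway_files(
            tmp_path,
            [("R1", "activation", "E"), ("R2", "inhibition", "E")],
            [("R1", "g1", "P"), ("R2", "g2", "P"), ("E", "g3", "P")],
        )
        (g,) = parse_pathways(sif, nm)
        (c,) = decompose_circuits(g)
        assert set(c.subgraph.nodes) == {"R1", "R2", "E"}

    def test_unknown_relation_errors(self, tmp_path):
        sif, nm = write_pathway_files(
            tmp_path, [("A", "binding", "B")], [("A", "g1", "P"), ("B", "g2", "P")]
        )
        with pytest.raises(ValueError, match="binding"):
            parse_pathways(sif, nm)

    def test_cycle_rejected_naming_cycle(self, tmp_path):
        sif, nm = write_pathway_files(
            tmp_path,
            [("A", "activation", "B"), ("B", "activation", "A")],
            [("A", "g1", "P"), ("B", "g2", "P")],
        )
        with pytest.raises(ValueError, match="cycle"):
            parse_pathways(sif, nm)

    def test_multi_gene_nodes_collected(self, tmp_path):
        sif, nm = write_pathway_files(
            tmp_path,
            [("A", "activation", "B")],
            [("A", "g1", "P"), ("A", "g2", "P"), ("B", "g3", "P")],
        )
        (g,) = parse_pathways(sif, nm)
        assert g.graph.nodes["A"]["genes"] == ("g1", "g2")


class TestDecompose:
    def test_diamond_one_circuit_four_nodes(self, diamond):
        (c,) = decompose_circuits(diamond)
        assert set(c.subgraph.nodes) == {"A", "B", "C", "D"}
        assert c.subgraph.number_of_edges() == 4

    def test_two_effectors_two_circuits(self):
        g = make_graph("p", ["A", "B", "C"], [("A", "B", 1), ("A", "C", 1)])
        assert [c.effector for c in decompose_circuits(g)] == ["B", "C"]

    def test_isolated_node_skipped_with_warning(self):
        g = nx.DiGraph()
        g.add_node("A", genes=("gA",))
        g.add_node("X", genes=("gX",))
        g.add_node("B", genes=("gB",))
        g.add_edge("A", "B", sign=1)
        pg = PathwayGraph("p", g)
        with pytest.warns(UserWarning, match="unreachable"):
            circuits = decompose_circuits(pg)
        assert [c.effector for c in circuits] == ["B"]

    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_matches_path_enumeration_oracle(self, seed, n):
        g = random_dag(np.random.default_rng(seed), n)
        circuits = {c.effector: c for c in decompose_circuits(g)}
        for eff in g.effectors:
            nodes, edges = oracle_circuit_subgraph(g, eff)
            if not nodes:
                assert eff not in circuits
                continue
            c = circuits[eff]
            assert set(c.subgraph.nodes) == nodes
            assert set(c.subgraph.edges) == edges


class TestRankRescale:
    def test_small_matrix_hand_ranks(self):
        x = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
        out = rank_rescale(x)
        np.testing.assert_allclose(out.to_numpy(), [[0.2, 0.4], [0.6, 0.8]])

    def test_constant_matrix_all_half(self):
        out = rank_rescale(pd.DataFrame(np.full((3, 4), 7.0)))
        np.testing.assert_allclose(out.to_numpy(), 0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.random((5, 6)))
        pd.testing.assert_frame_equal(rank_rescale(x), rank_rescale(np.exp(x) * 3))

    def test_open_interval(self):
        rng = np.random.default_rng(1)
        out = rank_rescale(pd.DataFrame(rng.random((10, 10))))
        assert (out.to_numpy() > 0).all() and (out.to_numpy() < 1).all()

    def test_na_rejected(self):
        x = pd.DataFrame([[1.0, np.nan]])
        with pytest.raises(ValueError, match="NA"):
            rank_rescale(x)

    def test_per_gene_mode_ranks_rows_independently(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0], [100.0, 200.0, 300.0]])
        out = rank_rescale(x, RescaleConfig(per_gene=True))
        np.testing.assert_allclose(out.iloc[0], out.iloc[1])


class TestNodeValue:
    def test_single_gene(self):
        assert node_value(("g",), pd.Series({"g": 0.7})) == 0.7

    def test_mean_of_members(self):
        assert node_value(("a", "b"), pd.Series({"a": 0.2, "b": 0.8})) == pytest.approx(0.5)

    def test_absent_gene_errors(self):
        with pytest.raises(KeyError, match="missing"):
            node_value(("missing",), pd.Series({"g": 0.7}))


class TestPropagate:
    def test_chain_hand_evaluation(self, chain3):
        (c,) = decompose_circuits(chain3)
        # chain: activity is the product of node values
        assert propagate(c, {"A": 0.5, "B": 1.0, "C": 1.0}) == pytest.approx(0.5, abs=1e-9)
        assert propagate(c, {"A": 0.5, "B": 0.5, "C": 0.5}) == pytest.approx(0.125, abs=1e-9)

    def test_annihilation_by_zero_on_only_path(self, chain3):
        (c,) = decompose_circuits(chain3)
        assert propagate(c, {"A": 0.0, "B": 0.9, "C": 0.9}) <= 1e-9

    def test_saturation_at_one(self, diamond):
        (c,) = decompose_circuits(diamond)
        assert propagate(c, {n: 1.0 for n in "ABCD"}) == pytest.approx(1.0, abs=1e-9)

    def test_inhibitor_attenuates(self):
        g = make_graph(
            "p", ["R", "I", "E"], [("R", "E", 1), ("I", "E", -1)]
        )
        (c,) = decompose_circuits(g)
        low = propagate(c, {"R": 0.8, "I": 0.1, "E": 0.9})
        high = propagate(c, {"R": 0.8, "I": 0.9, "E": 0.9})
        assert high < low

    @given(seed=st.integers(0, 5_000), n=st.integers(3, 10))
    @settings(max_examples=30)
    def test_monotone_in_activators_antitone_in_inhibitors(self, seed, n):
        rng = np.random.default_rng(seed)
        g = random_dag(rng, n)
        circuits = decompose_circuits(g)
        if not circuits:
            return
        c = circuits[rng.integers(len(circuits))]
        vals = {m: float(v) for m, v in zip(c.subgraph.nodes, rng.uniform(0.05, 0.95, c.subgraph.number_of_nodes()))}
        base = propagate(c, vals)
        node = list(c.subgraph.nodes)[rng.integers(c.subgraph.number_of_nodes())]
        bumped = dict(vals)
        bumped[node] = min(0.999, vals[node] + 0.2)
        new = propagate(c, bumped)
        # sign of effect determined by edge signs on node's paths to effector
        signs = set()
        for path in nx.all_simple_paths(c.subgraph, node, c.effector):
            n_inhib = sum(c.subgraph.edges[u, v]["sign"] < 0 for u, v in zip(path, path[1:]))
            signs.add(1 if n_inhib % 2 == 0 else -1)
        if node == c.effector:
            signs.add(1)
        if signs == {1}:
            assert new >= base - 1e-12
        elif signs == {-1}:
            assert new <= base + 1e-12

    def test_activity_in_open_interval(self, diamond):
        (c,) = decompose_circuits(diamond)
        a = propagate(c, {n: 0.5 for n in "ABCD"})
        assert 0.0 < a < 1.0


class TestActivityMatrix:
    def test_shape_and_labels(self, chain3, diamond):
        genes = sorted(chain3.genes | diamond.genes)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.random((len(genes), 3)), index=genes,
                            columns=["s1", "s2", "s3"])
        labels = pd.Series({"s1": "a", "s2": "a", "s3": "b"})
        ds = activity_matrix([chain3, diamond], rank_rescale(expr), labels)
        assert ds.activities.shape == (2, 3)
        assert list(ds.sample_groups) == ["a", "a", "b"]

    def test_duplicate_sample_columns_identical(self, chain3):
        genes = sorted(chain3.genes)
        expr = pd.DataFrame(
            np.tile(np.linspace(0.1, 0.9, len(genes))[:, None], (1, 2)),
            index=genes, columns=["s1", "s2"],
        )
        labels = pd.Series({"s1": "a", "s2": "a"})
        ds = activity_matrix([chain3], rank_rescale(expr), labels)
        assert ds.activities["s1"].equals(ds.activities["s2"])

    def test_planted_high_expression_sample_ranks_highest(self, diamond):
        genes = sorted(diamond.genes)
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.uniform(1, 2, (len(genes), 4)), index=genes,
                            columns=list("wxyz"))
        expr["z"] = 10.0  # uniformly higher expression, activator-only circuit
        labels = pd.Series({c: "g" for c in expr.columns})
        ds = activity_matrix([diamond], rank_rescale(expr), labels)
        assert ds.activities.loc["dia:D"].idxmax() == "z"

    def test_empty_circuit_list_errors(self):
        expr = pd.DataFrame([[0.5]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="no circuits"):
            activity_matrix([], expr, pd.Series({"s": "a"}))

    def test_missing_label_errors(self, chain3):
        genes = sorted(chain3.genes)
        expr = pd.DataFrame(np.full((len(genes), 1), 0.5), index=genes, columns=["s1"])
        with pytest.raises(ValueError, match="without a group"):
            activity_matrix([chain3], expr, pd.Series(dtype=object))
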