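"""PPI parsing, Eq.-style expression weighting, betweenness, differential edges."""

import numpy as np
import pandas as pd
import pytest

from netage import reference
from netage.expression_io import ExpressionDataset
from netage.ppi_diffnet import (
    PPIError,
    PPINetwork,
    differential_edges,
    edge_betweenness,
    extract_subnetworks,
    from_node_expression,
    overlay_expression,
    read_ppi,
)


def _edge_frame(rows):
    return pd.DataFrame(rows, columns=["source", "target", "directed"])


def _uniform_network(edges, value=1.0, conditions=("young", "ad")):
    topo = PPINetwork(_edge_frame([(u, v, 0) for u, v in edges]))
    expr = pd.DataFrame(
        {c: [value] * len(topo.nodes) for c in conditions}, index=topo.nodes
    )
    return from_node_expression(topo, expr)


def test_read_ppi_round_trip(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text(
        "source\ttarget\tdirected\nA\tB\t0\nB\tC\t1\nC\tD\t0\nD\tA\t1\n"
    )
    net = read_ppi(path)
    assert net.n_edges == 4
    assert sorted(net.edges["directed"]) == [0, 0, 1, 1]


def test_read_ppi_removes_self_loops_and_duplicates(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("A\tA\t0\nA\tB\t0\nB\tA\t0\nA\tB\t0\n")
    net = read_ppi(path)
    # the self-loop is dropped; A-B stored once (bidirectional, unordered)
    assert net.n_edges == 1
    assert net.nodes == ["A", "B"]


def test_read_ppi_reports_bad_lines(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("A\tB\t0\njunk_line_without_tabs\n")
    with pytest.raises(PPIError, match="2"):
        read_ppi(path)


def _expression_dataset():
    samples = ["y1", "y2", "a1", "a2"]
    matrix = pd.DataFrame(
        {
            "y1": [1.0, 1.0, 2.0],
            "y2": [1.0, 1.0, 2.0],
            "a1": [2.0, 1.0, 2.0],
            "a2": [2.0, 1.0, 2.0],
        },
        index=["A", "B", "C"],
    )
    meta = pd.DataFrame(
        {"group": ["young", "young", "ad", "ad"], "age": 50.0, "sex": "F"},
        index=samples,
    )
    return ExpressionDataset(matrix, meta)


def test_overlay_computes_reciprocal_product_weights():
    topo = PPINetwork(_edge_frame([("A", "B", 0), ("B", "C", 0)]))
    net = overlay_expression(topo, _expression_dataset(), mode="group_mean")
    # log2 values exponentiate to linear intensities 2, 2, 4
    w = net.edge_weights("young")
    labels = [f"{r.source}|{r.target}" for r in net.topology.edges.itertuples(index=False)]
    w = dict(zip(labels, w))
    assert w["A|B"] == pytest.approx(1 / (2 * 2))
    assert w["B|C"] == pytest.approx(1 / (2 * 4))


def test_doubling_one_endpoint_halves_incident_edge_weights():
    topo = PPINetwork(_edge_frame([("A", "B", 0), ("A", "C", 0), ("B", "C", 0)]))
    net = overlay_expression(topo, _expression_dataset(), mode="group_mean")
    w_young = net.edge_weights("young")
    w_ad = net.edge_weights("ad")  # gene A doubles from young to ad
    labels = [f"{r.source}|{r.target}" for r in net.topology.edges.itertuples(index=False)]
    ratios = dict(zip(labels, w_ad / w_young))
    assert ratios["A|B"] == pytest.approx(0.5)
    assert ratios["A|C"] == pytest.approx(0.5)
    assert ratios["B|C"] == pytest.approx(1.0)


def test_overlay_requires_shared_genes():
    topo = PPINetwork(_edge_frame([("X", "Y", 0)]))
    with pytest.raises(PPIError, match="overlap"):
        overlay_expression(topo, _expression_dataset())


def test_path_graph_betweenness_by_enumeration():
    net = _uniform_network([("a", "b"), ("b", "c")])
    scores = edge_betweenness(net, "young")
    # pairs {a,b} and {a,c} cross (a,b); {b,c} and {a,c} cross (b,c)
    assert scores["a|b"] == pytest.approx(2.0)
    assert scores["b|c"] == pytest.approx(2.0)


def test_star_graph_betweenness():
    net = _uniform_network([("c", f"l{i}") for i in range(4)])
    scores = edge_betweenness(net, "young")
    assert np.allclose(scores.to_numpy(), 4.0)


def test_tied_shortest_paths_split_credit_on_a_cycle():
    net = _uniform_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
    scores = edge_betweenness(net, "young")
    # on a 4-cycle each opposite pair has two tied 2-edge paths (0.5 each);
    # exhaustive enumeration is the oracle
    ref = reference.edge_betweenness_reference(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("d", "a", 1.0)]
    )
    for (u, v), val in ref.items():
        key = f"{u}|{v}" if f"{u}|{v}" in scores.index else f"{v}|{u}"
        assert scores[key] == pytest.approx(val, abs=1e-9)
    # each edge: its endpoint pair (1) plus half-credit for both opposite pairs
    assert scores["a|b"] == pytest.approx(2.0)


def test_directed_edges_only_carry_paths_in_their_direction():
    topo = PPINetwork(_edge_frame([("a", "b", 1), ("b", "c", 1)]))
    expr = pd.DataFrame({"young": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
    net = from_node_expression(topo, expr)
    scores = edge_betweenness(net, "young")
    # ordered reachable pairs: (a,b), (b,c), (a,c)
    assert scores["a|b"] == pytest.approx(2.0)
    assert scores["b|c"] == pytest.approx(2.0)
    ref = reference.edge_betweenness_reference(
        [("a", "b", 1.0), ("b", "c", 1.0)], directed=True
    )
    assert scores["a|b"] == pytest.approx(ref[("a", "b")])


def test_global_scaling_of_expression_leaves_betweenness_unchanged():
    rng = np.random.default_rng(0)
    edges = [(f"n{i}", f"n{j}") for i in range(10) for j in range(i + 1, 10) if rng.random() < 0.4]
    topo = PPINetwork(_edge_frame([(u, v, 0) for u, v in edges]))
    expr = pd.DataFrame({"young": rng.uniform(1, 16, len(topo.nodes))}, index=topo.nodes)
    base = edge_betweenness(from_node_expression(topo, expr), "young")
    scaled = edge_betweenness(from_node_expression(topo, expr * 3.7), "young")
    assert np.array_equal(base.to_numpy(), scaled.to_numpy())


def test_identical_conditions_flag_no_edges():
    rng = np.random.default_rng(1)
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d"), ("b", "d")]
    topo = PPINetwork(_edge_frame([(u, v, 0) for u, v in edges]))
    samples = [f"s{i}" for i in range(8)]
    expr = pd.DataFrame(
        np.tile(rng.uniform(2, 8, size=(len(topo.nodes), 1)), (1, 8)),
        index=topo.nodes,
        columns=samples,
    )
    groups = dict(zip(samples, ["young"] * 4 + ["ad"] * 4))
    net = from_node_expression(topo, expr, mode="per_sample", column_groups=groups)
    table = differential_edges(net, "young", "ad", diff_threshold=0.0)
    assert table["passes"].sum() == 0
    assert np.allclose(table["delta"], 0.0)


def test_threshold_and_significance_are_both_required():
    # a 5-cycle where one node's expression jumps: shortest paths reroute
    # through the cheap corner, shifting betweenness significantly
    rng = np.random.default_rng(2)
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")]
    topo = PPINetwork(_edge_frame([(u, v, 0) for u, v in edges]))
    samples = [f"s{i}" for i in range(12)]
    base = rng.uniform(2, 4, size=(len(topo.nodes), 12))
    expr = pd.DataFrame(base, index=topo.nodes, columns=samples)
    expr.loc["a", samples[6:]] *= 6.0  # clear, significant change on a's edges
    groups = dict(zip(samples, ["young"] * 6 + ["ad"] * 6))
    net = from_node_expression(topo, expr, mode="per_sample", column_groups=groups)
    loose = differential_edges(net, "young", "ad", diff_threshold=0.0, alpha=0.05)
    assert loose["passes"].any()
    sig_delta = loose.loc[loose["passes"], "delta"].abs().max()
    strict = differential_edges(
        net, "young", "ad", diff_threshold=sig_delta * 10, alpha=0.05
    )
    # still significant, but below the magnitude threshold -> not flagged
    assert strict["passes"].sum() == 0


def test_global_paired_mode_reports_network_level_statistic():
    net = _uniform_network([("a", "b"), ("b", "c"), ("c", "d")], value=2.0)
    table = differential_edges(
        net, "young", "ad", diff_threshold=0.0, mode="global_paired"
    )
    assert table["t"].nunique() == 1
    assert (table["betweenness_a"] == table["betweenness_b"]).all()


def test_subnetworks_split_by_direction_and_rank_hubs():
    table = pd.DataFrame(
        {
            "source": ["v", "v", "v", "x"],
            "target": ["a", "b", "c", "y"],
            "delta": [10.0, 11.0, 12.0, -9.0],
            "passes": [True, True, True, True],
            "direction": ["up", "up", "up", "down"],
            "product_delta": [1.0, 1.0, 1.0, -1.0],
        },
        index=["v|a", "v|b", "v|c", "x|y"],
    )
    subs = extract_subnetworks(table)
    assert len(subs["up"]["edges"]) == 3
    assert subs["up"]["hubs"][0] == "v"
    assert len(subs["down"]["edges"]) == 1
    assert set(subs["down"]["degree"]) == {"x", "y"}


def test_empty_table_gives_empty_subnetworks():
    table = pd.DataFrame(
        columns=["source", "target", "delta", "passes", "direction", "product_delta"]
    )
    subs = extract_subnetworks(table)
    assert subs["up"]["hubs"] == [] and subs["down"]["hubs"] == []
    assert len(subs["up"]["edges"]) == 0


def test_mixed_direction_edges_follow_product_change_sign():
    table = pd.DataFrame(
        {
            "source": ["a", "c"],
            "target": ["b", "d"],
            "delta": [10.0, 10.0],
            "passes": [True, True],
            "direction": ["mixed", "mixed"],
            "product_delta": [2.0, -2.0],
        },
        index=["a|b", "c|d"],
    )
    subs = extract_subnetworks(table)
    assert list(subs["up"]["edges"]["source"]) == ["a"]
    assert list(subs["down"]["edges"]["source"]) == ["c"]
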