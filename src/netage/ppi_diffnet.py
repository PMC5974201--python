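"""Expression-weighted PPI networks and differential edge connectivity.

A protein-protein interaction network is overlaid with condition-specific
expression: each node carries the (linear-scale) normalized signal intensity
N_i of its gene in a condition, and each edge the weight

    W_ij = 1 / (N_i * N_j).

Treating W as a distance makes highly co-expressed pairs cheap to traverse, so
weighted edge-betweenness centrality concentrates on high-expression
"corridors" — the active interactions of that condition.  Comparing per-edge
betweenness between conditions, with a magnitude threshold and BH-corrected
significance, yields differentially connected edges, which are split into
up- and downregulated subnetworks whose high-degree nodes are reported as
hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionDataset

logger = logging.getLogger(__name__)


class PPIError(ValueError):
    pass


@dataclass
class PPINetwork:
    """Interaction topology: edges with a directed flag, stored once each."""

    edges: pd.DataFrame  # columns: source, target, directed (0 = bidirectional)
    isolates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"source", "target", "directed"}
        if not required <= set(self.edges.columns):
            raise PPIError(f"edge table needs columns {sorted(required)}")
        loops = self.edges["source"] == self.edges["target"]
        if loops.any():
            logger.info("removing %d self-loop(s)", int(loops.sum()))
            self.edges = self.edges[~loops]
        before = len(self.edges)
        # bidirectional edges are unordered: canonicalize before deduplication
        canon = self.edges.copy()
        flip = (canon["directed"] == 0) & (canon["source"] > canon["target"])
        canon.loc[flip, ["source", "target"]] = canon.loc[
            flip, ["target", "source"]
        ].to_numpy()
        canon = canon.drop_duplicates(subset=["source", "target", "directed"])
        if len(canon) < before:
            logger.info("deduplicated %d edge(s)", before - len(canon))
        self.edges = canon.reset_index(drop=True)

    @property
    def nodes(self) -> list[str]:
        return sorted(
            set(self.edges["source"]) | set(self.edges["target"]) | set(self.isolates)
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_undirected(self) -> bool:
        return bool((self.edges["directed"] == 0).all())

    def subset_nodes(self, keep: Sequence[str]) -> "PPINetwork":
        keep_set = set(keep)
        mask = self.edges["source"].isin(keep_set) & self.edges["target"].isin(keep_set)
        return PPINetwork(self.edges[mask].reset_index(drop=True))


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI edge list (3-column TSV: source, target, directed-flag) or GraphML."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = ig.Graph.Read_GraphML(str(path))
        names = g.vs["name"] if "name" in g.vs.attributes() else [str(i) for i in range(g.vcount())]
        rows = [
            (names[e.source], names[e.target], int(g.is_directed()))
            for e in g.es
        ]
        return PPINetwork(pd.DataFrame(rows, columns=["source", "target", "directed"]))
    rows = []
    bad: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[:2] == ["source", "target"]:
                continue
            if len(parts) < 2:
                bad.append(ln)
                continue
            directed = 0
            if len(parts) >= 3:
                try:
                    directed = int(parts[2])
                except ValueError:
                    bad.append(ln)
                    continue
            rows.append((parts[0], parts[1], directed))
    if bad:
        raise PPIError(f"{path}: unparseable rows at lines {bad[:10]}")
    if not rows:
        raise PPIError(f"{path}: no edges parsed")
    return PPINetwork(pd.DataFrame(rows, columns=["source", "target", "directed"]))


@dataclass
class WeightedPPINetwork:
    """Topology plus per-condition (or per-sample) node weights.

    ``node_weights`` is genes x columns where columns are condition names in
    ``group_mean`` mode or sample IDs in ``per_sample`` mode;
    ``column_groups`` maps each column to its sample group.
    """

    topology: PPINetwork
    node_weights: pd.DataFrame
    mode: str  # "group_mean" | "per_sample"
    column_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.node_weights.to_numpy() <= 0).any():
            raise PPIError("node weights must be strictly positive")

    def conditions(self) -> list[str]:
        return list(self.node_weights.columns)

    def columns_for_group(self, group: str) -> list[str]:
        if self.mode == "group_mean":
            if group not in self.node_weights.columns:
                raise PPIError(f"no condition column {group!r}")
            return [group]
        return [c for c, g in self.column_groups.items() if g == group]

    def edge_weights(self, column: str) -> np.ndarray:
        """W_ij = 1 / (N_i * N_j) for every stored edge under one weight column."""
        n = self.node_weights[column]
        w_src = n.loc[self.topology.edges["source"]].to_numpy(dtype=float)
        w_tgt = n.loc[self.topology.edges["target"]].to_numpy(dtype=float)
        return 1.0 / (w_src * w_tgt)


def overlay_expression(
    network: PPINetwork,
    dataset: ExpressionDataset,
    mode: str = "group_mean",
    expression_scale: str = "log2",
) -> WeightedPPINetwork:
    """Map expression onto the PPI as per-condition node weights.

    Log-scale input (``expression_scale="log2"``) is exponentiated to linear
    intensity first.  Network nodes without expression are dropped together
    with their edges (logged).  In ``group_mean`` mode N_i(condition) is the
    mean linear intensity over that group's samples; ``per_sample`` keeps one
    weight vector per sample.
    """
    if mode not in ("group_mean", "per_sample"):
        raise PPIError(f"unknown overlay mode {mode!r}")
    if expression_scale not in ("log2", "linear"):
        raise PPIError(f"unknown expression scale {expression_scale!r}")
    present = [g for g in network.nodes if g in set(dataset.genes)]
    if not present:
        raise PPIError("no overlap between network nodes and dataset genes")
    dropped = len(network.nodes) - len(present)
    if dropped:
        logger.info("dropping %d network node(s) without expression", dropped)
    topo = network.subset_nodes(present)
    nodes = topo.nodes
    expr = dataset.matrix.loc[nodes]
    linear = np.power(2.0, expr) if expression_scale == "log2" else expr.copy()

    meta = dataset.sample_meta
    if mode == "group_mean":
        cols = {}
        groups = list(dict.fromkeys(meta["group"]))
        for g in groups:
            cols[g] = linear[meta.index[meta["group"] == g]].mean(axis=1)
        weights = pd.DataFrame(cols)
        column_groups = {g: g for g in groups}
    else:
        weights = linear
        column_groups = dict(meta["group"])
    return WeightedPPINetwork(
        topology=topo, node_weights=weights, mode=mode, column_groups=column_groups
    )


def from_node_expression(
    network: PPINetwork,
    node_expression: pd.DataFrame,
    mode: str = "group_mean",
    column_groups: Mapping[str, str] | None = None,
) -> WeightedPPINetwork:
    """Weighted network from precomputed linear-scale node expression columns."""
    present = [g for g in network.nodes if g in node_expression.index]
    topo = network.subset_nodes(present)
    weights = node_expression.loc[topo.nodes]
    cg = dict(column_groups) if column_groups else {c: c for c in weights.columns}
    return WeightedPPINetwork(
        topology=topo, node_weights=weights, mode=mode, column_groups=cg
    )


# ---------------------------------------------------------------------------
# Weighted edge betweenness
# ---------------------------------------------------------------------------

def _build_igraph(topo: PPINetwork) -> tuple[ig.Graph, list[int], bool]:
    """igraph view of the topology.

    Undirected networks map edge-for-edge.  Mixed/directed networks become a
    directed graph where a bidirectional edge contributes two reciprocal arcs;
    ``arc_owner[j]`` is the stored-edge index arc j belongs to.
    """
    nodes = topo.nodes
    idx = {g: i for i, g in enumerate(nodes)}
    undirected = topo.is_undirected
    arcs: list[tuple[int, int]] = []
    arc_owner: list[int] = []
    for e, row in enumerate(topo.edges.itertuples(index=False)):
        s, t = idx[row.source], idx[row.target]
        arcs.append((s, t))
        arc_owner.append(e)
        if not undirected and row.directed == 0:
            arcs.append((t, s))
            arc_owner.append(e)
    g = ig.Graph(n=len(nodes), edges=arcs, directed=not undirected)
    g.vs["name"] = nodes
    return g, arc_owner, undirected


def edge_betweenness(network: WeightedPPINetwork, column: str) -> pd.Series:
    """Weighted edge-betweenness per stored edge under one weight column.

    Edge weights act as distances (W = 1/(N_i N_j), so high joint expression
    means short).  Shortest paths between every pair of distinct reachable
    nodes are counted with fractional attribution across ties; pairs are
    unordered for undirected networks and ordered for directed ones.  For a
    bidirectional edge in a directed network the two reciprocal arcs' scores
    are summed.
    """
    w = network.edge_weights(column)
    if (w <= 0).any():
        raise PPIError("edge weights must be > 0 to act as distances")
    # betweenness is invariant to a global rescaling of the distances, and
    # normalizing keeps them well away from igraph's numerical epsilon
    w = w / w.min()
    g, arc_owner, undirected = _build_igraph(network.topology)
    arc_w = [float(w[o]) for o in arc_owner]
    scores = g.edge_betweenness(directed=not undirected, weights=arc_w)
    out = np.zeros(network.topology.n_edges)
    for arc, owner in enumerate(arc_owner):
        out[owner] += scores[arc]
    labels = [
        f"{r.source}|{r.target}"
        for r in network.topology.edges.itertuples(index=False)
    ]
    return pd.Series(out, index=labels, name=column)


def betweenness_matrix(
    network: WeightedPPINetwork, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Edge x column matrix of betweenness scores."""
    cols = list(columns) if columns is not None else network.conditions()
    return pd.DataFrame({c: edge_betweenness(network, c) for c in cols})


# ---------------------------------------------------------------------------
# Differential edges
# ---------------------------------------------------------------------------

def differential_edges(
    network: WeightedPPINetwork,
    condition_a: str,
    condition_b: str,
    diff_threshold: float = 2000.0,
    alpha: float = 0.05,
    mode: str = "per_sample_test",
    threshold_mode: str = "absolute",
) -> pd.DataFrame:
    """Test every edge for differential betweenness between two conditions.

    ``per_sample_test`` (default) computes one betweenness score per edge per
    sample (the network weighted by that sample's expression) and runs a
    Welch two-sample t-test per edge between the groups, BH-corrected across
    edges; an edge passes when |mean_b - mean_a| >= diff_threshold AND
    adjusted p < alpha.  ``global_paired`` runs a single paired t-test across
    all edges on the two condition-level score vectors (a whole-network
    statistic); per-edge passing then uses the magnitude threshold alone.

    ``threshold_mode="percentile"`` reinterprets *diff_threshold* as a
    percentile (e.g. 99) of the observed |delta| distribution, for networks
    far from the scale the absolute default was calibrated on.

    Direction is "up" when both endpoints' mean expression rises from a to b,
    "down" when both fall, else "mixed".
    """
    if mode not in ("per_sample_test", "global_paired"):
        raise PPIError(f"unknown mode {mode!r}")
    cols_a = network.columns_for_group(condition_a)
    cols_b = network.columns_for_group(condition_b)
    if mode == "per_sample_test":
        if network.mode != "per_sample":
            raise PPIError("per_sample_test requires a per_sample overlay")
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise PPIError("per_sample_test needs >= 2 samples per condition")
        B_a = betweenness_matrix(network, cols_a)
        B_b = betweenness_matrix(network, cols_b)
        mean_a = B_a.mean(axis=1)
        mean_b = B_b.mean(axis=1)
        delta = mean_b - mean_a
        tstat, p = stats.ttest_ind(
            B_b.to_numpy(), B_a.to_numpy(), axis=1, equal_var=False
        )
        p = np.where(np.isnan(p), 1.0, p)
        tstat = np.where(np.isnan(tstat), 0.0, tstat)
        adj_p = multipletests(p, method="fdr_bh")[1]
    else:
        if network.mode == "per_sample":
            raise PPIError("global_paired expects condition-level (group_mean) weights")
        b_a = edge_betweenness(network, cols_a[0])
        b_b = edge_betweenness(network, cols_b[0])
        mean_a, mean_b = b_a, b_b
        delta = b_b - b_a
        res = stats.ttest_rel(b_b.to_numpy(), b_a.to_numpy())
        t_val = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p_val = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        tstat = np.full(len(delta), t_val)
        p = np.full(len(delta), p_val)
        adj_p = p.copy()

    if threshold_mode == "percentile":
        thr = float(np.percentile(np.abs(delta), diff_threshold))
    elif threshold_mode == "absolute":
        thr = diff_threshold
    else:
        raise PPIError(f"unknown threshold_mode {threshold_mode!r}")

    big = np.abs(delta.to_numpy()) >= thr
    if mode == "per_sample_test":
        passes = big & (adj_p < alpha)
    else:
        passes = big

    # endpoint mean-expression change a -> b decides the direction class
    n_a = network.node_weights[cols_a].mean(axis=1)
    n_b = network.node_weights[cols_b].mean(axis=1)
    edges = network.topology.edges
    src = edges["source"].to_numpy()
    tgt = edges["target"].to_numpy()
    src_up = (n_b.loc[src].to_numpy() > n_a.loc[src].to_numpy())
    tgt_up = (n_b.loc[tgt].to_numpy() > n_a.loc[tgt].to_numpy())
    src_dn = (n_b.loc[src].to_numpy() < n_a.loc[src].to_numpy())
    tgt_dn = (n_b.loc[tgt].to_numpy() < n_a.loc[tgt].to_numpy())
    direction = np.where(
        src_up & tgt_up, "up", np.where(src_dn & tgt_dn, "down", "mixed")
    )
    # product change of N_i*N_j resolves mixed edges when subnetworks are built
    prod_delta = (
        n_b.loc[src].to_numpy() * n_b.loc[tgt].to_numpy()
        - n_a.loc[src].to_numpy() * n_a.loc[tgt].to_numpy()
    )

    return pd.DataFrame(
        {
            "source": src,
            "target": tgt,
            "betweenness_a": mean_a.to_numpy(),
            "betweenness_b": mean_b.to_numpy(),
            "delta": delta.to_numpy(),
            "t": tstat,
            "p": p,
            "adj_p": adj_p,
            "passes": passes,
            "direction": direction,
            "product_delta": prod_delta,
            "contrast": f"{condition_a}_vs_{condition_b}",
            "threshold": thr,
        },
        index=delta.index,
    )


# ---------------------------------------------------------------------------
# Subnetworks and hubs
# ---------------------------------------------------------------------------

def extract_subnetworks(
    table: pd.DataFrame, hub_percentile: float = 95.0
) -> dict[str, dict]:
    """Edge-induced up/down subnetworks of passing edges, with degree hubs.

    Mixed-direction edges are assigned by the sign of the N_i*N_j product
    change.  Hubs are nodes whose subnetwork degree reaches the
    *hub_percentile* of that subnetwork's degree distribution, ranked by
    degree with ties broken lexicographically.
    """
    result: dict[str, dict] = {}
    passing = table[table["passes"]] if not table.empty else table
    for direction in ("up", "down"):
        if passing.empty:
            sub = passing
        else:
            explicit = passing["direction"] == direction
            resolved_mixed = (passing["direction"] == "mixed") & (
                (passing["product_delta"] > 0)
                if direction == "up"
                else (passing["product_delta"] < 0)
            )
            sub = passing[explicit | resolved_mixed]
        degree: dict[str, int] = {}
        for row in sub.itertuples(index=False):
            degree[row.source] = degree.get(row.source, 0) + 1
            degree[row.target] = degree.get(row.target, 0) + 1
        if degree:
            cutoff = np.percentile(list(degree.values()), hub_percentile)
            hubs = sorted(
                (n for n, d in degree.items() if d >= cutoff),
                key=lambda n: (-degree[n], n),
            )
        else:
            hubs = []
        result[direction] = {
            "edges": sub.reset_index(drop=True),
            "degree": degree,
            "hubs": hubs,
        }
    return result
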