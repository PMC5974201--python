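"""Synthetic expression, marker and PPI generation with known planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: a log-intensity matrix over three sample groups (young / aging / AD)
containing block-correlated gene modules whose latent eigengene shifts
monotonically across groups, cell-type marker lists overlapping the planted
modules, and a scale-free protein interaction network whose node expression
can be perturbed on chosen edges in a chosen condition.  Every output is a
deterministic function of the spec and its seed.

Module construction uses a latent-factor model: each module ``m`` has a latent
factor ``F_m`` (unit variance across samples, plus a per-group mean offset),
and member gene ``i`` is

    x_i = baseline_i + sign_m * l_i * a_m * F_m + noise_sd * eps

with loadings ``l_i ~ U[0.7, 1]``.  The module amplitude ``a_m`` is calibrated
so the expected within-module Pearson correlation equals the requested
``base_correlation``: with ``E[l^2] = 0.73`` for U[0.7,1],

    a_m = noise_sd * sqrt(r / ((1 - r) * 0.73)).

This makes the first singular vector of the standardized block recover the
latent, which is exactly what the eigengene-by-SVD summary assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset, write_gmt

# E[l^2] for loadings uniform on [0.7, 1]
_MEAN_SQ_LOADING = (1.0**3 - 0.7**3) / (3 * 0.3)

AGE_RANGES = {"young": (20, 50), "aging": (70, 99), "ad": (70, 99)}


class SyntheticSpecError(ValueError):
    """Raised when a SyntheticSpec violates its invariants."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    base_correlation: float
    group_shift: tuple[float, float, float]  # latent mean offset per (young, aging, ad)
    sign: int = 1


@dataclass(frozen=True)
class PerturbedEdge:
    """Multiplicative expression change on both endpoints of a PPI edge."""

    edge: tuple[str, str]
    condition: str
    factor: float


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study; seed fixes all outputs."""

    n_genes: int = 2000
    n_samples_per_group: tuple[int, int, int] = (17, 21, 18)
    modules: Sequence[ModuleSpec] = ()
    noise_sd: float = 1.0
    marker_overlap: float = 0.8
    marker_list_length: int | None = None
    ppi_n_nodes: int = 0  # 0 disables PPI generation
    ppi_attach_m: int = 2
    perturbed_edges: Sequence[PerturbedEdge] = ()
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SyntheticSpecError("n_genes must be positive")
        if any(n < 1 for n in self.n_samples_per_group):
            raise SyntheticSpecError("n_samples_per_group entries must be positive")
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise SyntheticSpecError(
                f"module sizes sum to {total} > n_genes={self.n_genes}"
            )
        for i, m in enumerate(self.modules):
            if not 0 < m.base_correlation < 1:
                raise SyntheticSpecError(
                    f"modules[{i}].base_correlation={m.base_correlation} not in (0,1)"
                )
            if m.sign not in (-1, 1):
                raise SyntheticSpecError(f"modules[{i}].sign must be +1 or -1")
            if len(m.group_shift) != 3:
                raise SyntheticSpecError(f"modules[{i}].group_shift needs 3 entries")
        if self.noise_sd <= 0:
            raise SyntheticSpecError("noise_sd must be > 0")
        if not 0 <= self.marker_overlap <= 1:
            raise SyntheticSpecError(
                f"marker_overlap={self.marker_overlap} outside [0, 1]"
            )
        if self.ppi_n_nodes > 0 and self.ppi_n_nodes > self.n_genes:
            raise SyntheticSpecError("ppi_n_nodes must be <= n_genes")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside generated data for benchmarking."""

    module_labels: dict[str, int]              # gene -> module id (0 = background)
    module_signs: dict[int, int]
    group_shifts: dict[int, tuple[float, float, float]]
    latents: pd.DataFrame | None = None        # module x sample latent factors
    perturbed_edges: list[PerturbedEdge] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_labels": self.module_labels,
            "module_signs": {str(k): v for k, v in self.module_signs.items()},
            "group_shifts": {str(k): list(v) for k, v in self.group_shifts.items()},
            "perturbed_edges": [
                {"edge": list(p.edge), "condition": p.condition, "factor": p.factor}
                for p in self.perturbed_edges
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_labels={g: int(m) for g, m in payload["module_labels"].items()},
            module_signs={int(k): int(v) for k, v in payload["module_signs"].items()},
            group_shifts={
                int(k): tuple(v) for k, v in payload["group_shifts"].items()
            },
            perturbed_edges=[
                PerturbedEdge(tuple(p["edge"]), p["condition"], p["factor"])
                for p in payload["perturbed_edges"]
            ],
        )


def module_amplitude(base_correlation: float, noise_sd: float) -> float:
    """Latent amplitude giving an expected within-module correlation of *base_correlation*."""
    r = base_correlation
    return noise_sd * np.sqrt(r / ((1 - r) * _MEAN_SQ_LOADING))


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a genes x samples log-intensity matrix with planted modules."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_y, n_a, n_d = spec.n_samples_per_group
    n_samples = n_y + n_a + n_d
    groups = ["young"] * n_y + ["aging"] * n_a + ["ad"] * n_d
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]

    ages = np.empty(n_samples)
    for g in ("young", "aging", "ad"):
        idx = [i for i, grp in enumerate(groups) if grp == g]
        lo, hi = AGE_RANGES[g]
        ages[idx] = rng.uniform(lo, hi, size=len(idx))
    sexes = ["F" if i % 2 == 0 else "M" for i in range(n_samples)]

    baseline = rng.uniform(*spec.baseline_range, size=spec.n_genes)
    X = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))

    labels = {g: 0 for g in genes}
    signs: dict[int, int] = {}
    shifts: dict[int, tuple[float, float, float]] = {}
    latents = {}
    group_idx = {g: np.array([i for i, grp in enumerate(groups) if grp == g]) for g in GROUP_ORDER}

    offset = 0
    for mid, mod in enumerate(spec.modules, start=1):
        latent = rng.normal(0.0, 1.0, size=n_samples)
        for g, shift in zip(GROUP_ORDER, mod.group_shift):
            latent[group_idx[g]] += shift
        loadings = rng.uniform(0.7, 1.0, size=mod.size)
        amp = module_amplitude(mod.base_correlation, spec.noise_sd)
        rows = slice(offset, offset + mod.size)
        X[rows, :] += mod.sign * amp * loadings[:, None] * latent[None, :]
        for g in genes[offset : offset + mod.size]:
            labels[g] = mid
        signs[mid] = mod.sign
        shifts[mid] = tuple(mod.group_shift)
        latents[mid] = latent
        offset += mod.size

    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=sample_ids)
    meta = pd.DataFrame(
        {"group": groups, "age": np.round(ages, 1), "sex": sexes},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        module_labels=labels,
        module_signs=signs,
        group_shifts=shifts,
        latents=pd.DataFrame(latents, index=sample_ids).T if latents else None,
        perturbed_edges=list(spec.perturbed_edges),
    )
    return ExpressionDataset(matrix, meta), truth


GROUP_ORDER = ("young", "aging", "ad")


def generate_markers(
    spec: SyntheticSpec, dataset: ExpressionDataset, truth: GroundTruth
) -> dict[str, list[str]]:
    """One marker list per planted module: a fraction copied from the module,
    padded with background genes; lists are mutually disjoint."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    background = [g for g, m in truth.module_labels.items() if m == 0]
    rng.shuffle(background)
    bg_cursor = 0
    markers: dict[str, list[str]] = {}
    for mid in sorted(truth.module_signs):
        module_genes = sorted(
            g for g, m in truth.module_labels.items() if m == mid
        )
        n_from_module = int(round(spec.marker_overlap * len(module_genes)))
        length = spec.marker_list_length or len(module_genes)
        chosen = list(rng.choice(module_genes, size=n_from_module, replace=False))
        n_pad = max(0, length - len(chosen))
        if bg_cursor + n_pad > len(background):
            raise SyntheticSpecError("not enough background genes to pad marker lists")
        chosen += background[bg_cursor : bg_cursor + n_pad]
        bg_cursor += n_pad
        markers[f"celltype_{mid}"] = chosen[:length]
    return markers


@dataclass
class SyntheticPPI:
    """Scale-free PPI over a subset of dataset genes plus expression overlays.

    ``node_expression`` holds per-condition node weights (linear-scale group
    means, with planted perturbations applied); ``sample_expression`` holds the
    matching per-sample linear intensities so per-sample network tests see the
    same perturbation.
    """

    graph: nx.Graph                    # nodes are gene symbols
    node_expression: pd.DataFrame      # genes x conditions (linear scale)
    sample_expression: pd.DataFrame    # genes x samples (linear scale)
    perturbed_edges: list[PerturbedEdge]

    def edge_list(self) -> pd.DataFrame:
        rows = [(u, v, 0) for u, v in self.graph.edges()]
        return pd.DataFrame(rows, columns=["source", "target", "directed"])

    def write_edge_list(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)


def generate_ppi(
    spec: SyntheticSpec, dataset: ExpressionDataset, truth: GroundTruth | None = None
) -> SyntheticPPI:
    """Preferential-attachment PPI whose node expression tracks the dataset.

    Node expression is the per-group mean linear intensity (2**log2) of the
    gene; each perturbed edge multiplies both endpoints' expression by the
    stated factor in the stated condition only (group-mean and per-sample
    overlays alike).
    """
    spec.validate()
    if spec.ppi_n_nodes < 1:
        raise SyntheticSpecError("ppi_n_nodes must be >= 1 to generate a PPI")
    if spec.ppi_n_nodes > dataset.n_genes:
        raise SyntheticSpecError("ppi_n_nodes exceeds the dataset gene count")
    rng = np.random.default_rng(spec.seed + 2)
    node_genes = sorted(
        rng.choice(dataset.genes.to_numpy(), size=spec.ppi_n_nodes, replace=False)
    )
    g_int = nx.barabasi_albert_graph(
        spec.ppi_n_nodes, spec.ppi_attach_m, seed=int(spec.seed % (2**31))
    )
    graph = nx.relabel_nodes(g_int, dict(enumerate(node_genes)))

    linear = np.power(2.0, dataset.matrix.loc[node_genes])
    sample_expr = linear.copy()
    meta = dataset.sample_meta

    for pert in spec.perturbed_edges:
        u, v = pert.edge
        if not graph.has_edge(u, v):
            raise SyntheticSpecError(
                f"perturbed edge ({u}, {v}) not present in generated topology"
            )
        cond_samples = meta.index[meta["group"] == pert.condition]
        if len(cond_samples) == 0:
            raise SyntheticSpecError(f"no samples in condition {pert.condition!r}")
        for gene in (u, v):
            sample_expr.loc[gene, cond_samples] *= pert.factor

    cond_expr = {}
    for g in GROUP_ORDER:
        cols = meta.index[meta["group"] == g]
        cond_expr[g] = sample_expr[cols].mean(axis=1)
    node_expression = pd.DataFrame(cond_expr)

    return SyntheticPPI(
        graph=graph,
        node_expression=node_expression,
        sample_expression=sample_expr,
        perturbed_edges=list(spec.perturbed_edges),
    )


def write_all(
    spec: SyntheticSpec,
    out_dir: str | Path,
    with_ppi: bool = True,
) -> dict[str, Path]:
    """Generate and serialize the full synthetic study to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_expression(spec)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "markers": out / "markers.gmt",
        "truth": out / "truth.json",
    }
    dataset.to_tsv(paths["expression"], paths["metadata"])
    markers = generate_markers(spec, dataset, truth)
    write_gmt(markers, paths["markers"])
    truth.to_json(paths["truth"])
    if with_ppi:
        ppi = generate_ppi(spec, dataset, truth)
        paths["ppi"] = out / "ppi_edges.tsv"
        ppi.write_edge_list(paths["ppi"])
    return paths
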