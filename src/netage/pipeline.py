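"""End-to-end orchestration: expression -> modules -> statistics -> PPI edges.

A :class:`RunConfig` names either real input files (expression + metadata,
optional PPI edge list and marker GMT) or a synthetic spec, plus every stage
parameter.  :func:`run_pipeline` executes the stages in order, writes each
stage's tables under the output directory, and records a manifest (seed,
parameters, input checksums) so a rerun with the same config reproduces every
output byte-for-byte.  :func:`benchmark_report` compares a synthetic run
against its ground-truth sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .coexpression import build_module_set, intramodular_hubs
from .expression_io import ExpressionDataset, read_gmt
from .module_stats import (
    deg_filter,
    moderated_ttest,
    module_preservation,
    overlap_table,
    preservation_frame,
)
from .ppi_diffnet import (
    PPINetwork,
    differential_edges,
    extract_subnetworks,
    from_node_expression,
    read_ppi,
)
from .synthetic import GroundTruth, SyntheticSpec, generate_expression, generate_markers, generate_ppi

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, completed: list[str]):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.completed = completed


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run.

    Exactly one of (``expression_path`` + ``metadata_path``) or
    ``synthetic_spec`` must be set.
    """

    out_dir: str | Path = "results/run"
    expression_path: str | Path | None = None
    metadata_path: str | Path | None = None
    ppi_path: str | Path | None = None
    marker_gmt_path: str | Path | None = None
    synthetic_spec: SyntheticSpec | None = None
    # coexpression
    powers: tuple[int, ...] = tuple(range(1, 31))
    r2_threshold: float = 0.8
    min_module_size: int = 150
    cut_quantile: float = 0.99
    iqr_threshold: float | None = None
    # module stats
    fc_threshold: float = 1.5
    fdr: float = 0.05
    n_perm: int = 100
    # ppi
    diff_threshold: float = 2000.0
    threshold_mode: str = "absolute"
    alpha: float = 0.05
    overlay_mode: str = "per_sample"
    contrasts: tuple[tuple[str, str], ...] = (
        ("young", "aging"),
        ("aging", "ad"),
        ("young", "ad"),
    )
    seed: int = 0

    def validate(self) -> None:
        real = self.expression_path is not None
        synth = self.synthetic_spec is not None
        if real == synth:
            raise ValueError(
                "exactly one of real inputs (expression_path) or synthetic_spec required"
            )
        if real and self.metadata_path is None:
            raise ValueError("metadata_path required with expression_path")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if not 0 < self.cut_quantile <= 1:
            raise ValueError("cut_quantile must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        for p in (self.fdr, self.alpha):
            if not 0 < p < 1:
                raise ValueError("fdr/alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("synthetic_spec",) and not isinstance(v, Path)
        },
        "inputs": {},
        "stages": {},
    }

    # stage 1: expression
    truth: GroundTruth | None = None
    synthetic_ppi = None
    try:
        if config.synthetic_spec is not None:
            spec = config.synthetic_spec
            dataset, truth = generate_expression(spec)
            markers = generate_markers(spec, dataset, truth)
            truth.to_json(out / "truth.json")
            if spec.ppi_n_nodes > 0:
                synthetic_ppi = generate_ppi(spec, dataset, truth)
        else:
            dataset = ExpressionDataset.from_tsv(
                config.expression_path, config.metadata_path
            )
            for key in ("expression_path", "metadata_path", "ppi_path", "marker_gmt_path"):
                p = getattr(config, key)
                if p is not None:
                    manifest["inputs"][key] = _sha256(Path(p))
            markers = (
                read_gmt(config.marker_gmt_path) if config.marker_gmt_path else {}
            )
        if config.iqr_threshold is not None:
            from .expression_io import iqr_filter

            dataset = iqr_filter(dataset, config.iqr_threshold)
        dataset.to_tsv(out / "expression.tsv", out / "metadata.tsv")
        completed.append("expression_io")
        manifest["stages"]["expression_io"] = {
            "n_genes": dataset.n_genes,
            "n_samples": dataset.n_samples,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("expression_io", str(exc), completed) from exc

    # stage 2: coexpression
    try:
        modules, fit, power = build_module_set(
            dataset,
            powers=config.powers,
            r2_threshold=config.r2_threshold,
            min_module_size=config.min_module_size,
            cut_quantile=config.cut_quantile,
        )
        assign = pd.DataFrame(
            {"module": modules.labels, "kim": modules.kim}
        )
        assign.to_csv(out / "module_assignment.tsv", sep="\t", index_label="gene")
        if fit is not None:
            fit.table.to_csv(out / "scale_free_fit.tsv", sep="\t", index=False)
        if modules.eigengenes is not None:
            modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")
        if modules.trait_cor is not None:
            modules.trait_cor.to_csv(out / "module_trait_cor.tsv", sep="\t", index=False)
        completed.append("coexpression")
        manifest["stages"]["coexpression"] = {
            "power": power,
            "n_modules": len(modules.module_ids),
            "module_sizes": modules.sizes(),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coexpression", str(exc), completed) from exc

    # stage 3: module statistics
    try:
        deg_frames = []
        for a, b in config.contrasts:
            if dataset.group_samples(a) and dataset.group_samples(b):
                table = moderated_ttest(dataset, a, b)
                up, down = deg_filter(table, config.fc_threshold, config.fdr)
                table["deg"] = np.where(
                    table.index.isin(up), "up", np.where(table.index.isin(down), "down", "")
                )
                deg_frames.append(table.reset_index())
        if deg_frames:
            pd.concat(deg_frames).to_csv(out / "deg.tsv", sep="\t", index=False)
        if markers and modules.module_ids:
            universe = list(dataset.genes)
            marker_sets = {
                name: [g for g in genes if g in set(universe)]
                for name, genes in markers.items()
            }
            module_sets = {m: modules.module_genes(m) for m in modules.module_ids}
            overlaps = overlap_table(module_sets, marker_sets, universe)
            overlaps.to_csv(out / "celltype_overlap.tsv", sep="\t", index=False)
        if config.synthetic_spec is not None and modules.module_ids:
            rep_spec = SyntheticSpec(
                **{**vars(config.synthetic_spec), "seed": config.synthetic_spec.seed + 50_000}
            )
            replicate, _ = generate_expression(rep_spec)
            pres = module_preservation(
                dataset,
                modules.labels,
                replicate,
                power=power,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            preservation_frame(pres).to_csv(out / "preservation.tsv", sep="\t", index=False)
        completed.append("module_stats")
        manifest["stages"]["module_stats"] = {
            "contrasts": ["_vs_".join(c) for c in config.contrasts]
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("module_stats", str(exc), completed) from exc

    # stage 4: PPI differential connectivity
    try:
        network = None
        if synthetic_ppi is not None:
            topo = PPINetwork(synthetic_ppi.edge_list())
            network = from_node_expression(
                topo,
                synthetic_ppi.sample_expression
                if config.overlay_mode == "per_sample"
                else synthetic_ppi.node_expression,
                mode=config.overlay_mode,
                column_groups=dict(dataset.sample_meta["group"])
                if config.overlay_mode == "per_sample"
                else None,
            )
        elif config.ppi_path is not None:
            from .ppi_diffnet import overlay_expression

            topo = read_ppi(config.ppi_path)
            network = overlay_expression(topo, dataset, mode=config.overlay_mode)
        if network is not None:
            edge_frames = []
            hub_rows = []
            for a, b in config.contrasts:
                table = differential_edges(
                    network,
                    a,
                    b,
                    diff_threshold=config.diff_threshold,
                    alpha=config.alpha,
                    mode="per_sample_test"
                    if config.overlay_mode == "per_sample"
                    else "global_paired",
                    threshold_mode=config.threshold_mode,
                )
                edge_frames.append(table.reset_index(names="edge"))
                subnets = extract_subnetworks(table)
                for direction in ("up", "down"):
                    for rank, gene in enumerate(subnets[direction]["hubs"], 1):
                        hub_rows.append(
                            {
                                "contrast": f"{a}_vs_{b}",
                                "direction": direction,
                                "rank": rank,
                                "gene": gene,
                                "degree": subnets[direction]["degree"][gene],
                            }
                        )
            pd.concat(edge_frames).to_csv(out / "differential_edges.tsv", sep="\t", index=False)
            pd.DataFrame(hub_rows).to_csv(out / "subnetwork_hubs.tsv", sep="\t", index=False)
            manifest["stages"]["ppi_diffnet"] = {
                "n_edges": network.topology.n_edges,
                "n_nodes": len(network.topology.nodes),
            }
        completed.append("ppi_diffnet")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ppi_diffnet", str(exc), completed) from exc

    manifest["completed_stages"] = completed
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def benchmark_report(run_dir: str | Path, truth_path: str | Path | None = None) -> dict:
    """Compare a synthetic run's outputs against the planted ground truth."""
    run_dir = Path(run_dir)
    truth_path = Path(truth_path) if truth_path else run_dir / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(f"ground-truth sidecar not found: {truth_path}")
    truth = GroundTruth.from_json(truth_path)
    assign = pd.read_csv(run_dir / "module_assignment.tsv", sep="\t", index_col=0)
    genes = assign.index
    true_labels = np.array([truth.module_labels.get(g, 0) for g in genes])
    found = assign["module"].to_numpy()
    report: dict[str, Any] = {
        "module_ari": float(adjusted_rand_score(true_labels, found)),
        "n_modules_found": int(len(set(found) - {0})),
        "n_modules_planted": len(truth.module_signs),
    }
    trait_path = run_dir / "module_trait_cor.tsv"
    if trait_path.exists():
        tc = pd.read_csv(trait_path, sep="\t")
        hits = total = 0
        for mid, shifts in truth.group_shifts.items():
            planted = {g for g, m in truth.module_labels.items() if m == mid}
            best, best_ov = None, 0
            for fid in set(found) - {0}:
                ov = len(planted & set(genes[found == fid]))
                if ov > best_ov:
                    best, best_ov = fid, ov
            if best is None:
                continue
            row = tc[(tc["module"] == f"M{best}") & (tc["trait"] == "stage")]
            if row.empty:
                continue
            total += 1
            planted_dir = truth.module_signs[mid] * np.sign(shifts[2] - shifts[0])
            if np.sign(row["cor"].iloc[0]) == planted_dir:
                hits += 1
        report["stage_sign_accuracy"] = hits / total if total else float("nan")
    pres_path = run_dir / "preservation.tsv"
    if pres_path.exists():
        pres = pd.read_csv(pres_path, sep="\t")
        report["preservation_min_z"] = float(pres["z_summary"].min())
        report["preservation_classes"] = dict(
            zip(pres["module"].astype(str), pres["class"])
        )
    return report
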