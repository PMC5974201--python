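"""Simulate the synthetic hippocampal aging/AD study.

Generates the standard benchmark dataset — 2,000 genes over 17 young / 21
aging / 18 AD samples with four planted co-expression modules (two up- and
two downregulated across the young -> aging -> AD transition) — together
with cell-type marker lists overlapping the planted modules and a 200-node
scale-free PPI in which one hub edge is doubled in AD.  All files and the
ground-truth sidecar go to results/synthetic_study/.
"""

import sys
from pathlib import Path

from netage.benchmarks import perturbed_hub_study, standard_benchmark_spec
from netage.expression_io import write_gmt
from netage.synthetic import SyntheticSpec, generate_markers

OUT = Path("results/synthetic_study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = standard_benchmark_spec(SEED)
    spec = SyntheticSpec(**{**vars(spec), "ppi_n_nodes": 200, "ppi_attach_m": 2})
    dataset, truth, unperturbed, perturbed, (hub, nb) = perturbed_hub_study(spec)

    dataset.to_tsv(OUT / "expression.tsv", OUT / "metadata.tsv")
    write_gmt(generate_markers(spec, dataset, truth), OUT / "markers.gmt")
    perturbed.write_edge_list(OUT / "ppi_edges.tsv")
    perturbed.sample_expression.to_csv(OUT / "ppi_sample_expression.tsv", sep="\t")
    unperturbed.node_expression.to_csv(OUT / "ppi_node_expression_unperturbed.tsv", sep="\t")
    truth.perturbed_edges = list(perturbed.perturbed_edges)
    truth.to_json(OUT / "truth.json")

    print(f"wrote synthetic study to {OUT}")
    print(f"  genes x samples: {dataset.n_genes} x {dataset.n_samples}")
    print(f"  planted modules: {len(truth.module_signs)} "
          f"(sizes {[sum(1 for m in truth.module_labels.values() if m == i) for i in sorted(truth.module_signs)]})")
    print(f"  PPI: {perturbed.graph.number_of_nodes()} nodes, "
          f"{perturbed.graph.number_of_edges()} edges; "
          f"perturbed hub edge {hub}--{nb} (x2 in AD)")


if __name__ == "__main__":
    main()
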