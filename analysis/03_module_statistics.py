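"""Differential expression, cell-type enrichment and module preservation.

Runs moderated-t DEG analysis for the young/aging, aging/AD and young/AD
contrasts, tests each detected module for overlap with the cell-type marker
lists, and quantifies module preservation (Zsummary) against an independent
synthetic replicate.  Tables go to results/module_stats/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from netage.benchmarks import standard_benchmark_spec
from netage.expression_io import ExpressionDataset, read_gmt
from netage.module_stats import (
    deg_filter,
    moderated_ttest,
    module_preservation,
    overlap_table,
    preservation_frame,
)
from netage.synthetic import SyntheticSpec, generate_expression

IN = Path("results/synthetic_study")
MODULES = Path("results/modules")
OUT = Path("results/module_stats")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = ExpressionDataset.from_tsv(IN / "expression.tsv", IN / "metadata.tsv")
    labels = pd.read_csv(MODULES / "module_assignment.tsv", sep="\t", index_col=0)["module"]
    markers = read_gmt(IN / "markers.gmt")

    frames = []
    for a, b in (("young", "aging"), ("aging", "ad"), ("young", "ad")):
        table = moderated_ttest(dataset, a, b)
        up, down = deg_filter(table)
        print(f"{a} vs {b}: {len(up)} up, {len(down)} down DEGs "
              f"(fold change >= 1.5, BH-adjusted p < 0.05)")
        frames.append(table.reset_index())
    pd.concat(frames).to_csv(OUT / "deg.tsv", sep="\t", index=False)

    module_sets = {m: list(labels.index[labels == m]) for m in sorted(set(labels) - {0})}
    overlaps = overlap_table(module_sets, markers, list(dataset.genes))
    overlaps.to_csv(OUT / "celltype_overlap.tsv", sep="\t", index=False)
    enriched = overlaps[overlaps["p"] < 0.05]
    print(f"cell-type enrichment: {len(enriched)} of {len(overlaps)} module/set "
          f"pairs significant at p < 0.05")

    # preservation against an independent draw of the same planted design
    spec = standard_benchmark_spec(SEED)
    replicate, _ = generate_expression(
        SyntheticSpec(**{**vars(spec), "seed": spec.seed + 50_000})
    )
    power = int(json.loads((MODULES / "power.json").read_text())["power"])
    pres = preservation_frame(
        module_preservation(dataset, labels, replicate, power=power, n_perm=100, seed=SEED)
    )
    pres.to_csv(OUT / "preservation.tsv", sep="\t", index=False)
    for _, row in pres.iterrows():
        print(f"  module M{row['module']}: Zsummary = {row['z_summary']:.1f} ({row['class']})")


if __name__ == "__main__":
    main()
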