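"""Score the whole analysis against the planted ground truth.

Compares the module assignment, trait-correlation signs, preservation classes
and differential-edge calls produced by the previous steps with the
ground-truth sidecar, and prints the recovery metrics.  Writes
results/benchmark_summary.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from netage.synthetic import GroundTruth

STUDY = Path("results/synthetic_study")
MODULES = Path("results/modules")
STATS = Path("results/module_stats")
DIFF = Path("results/ppi_diffnet")


def main() -> None:
    truth = GroundTruth.from_json(STUDY / "truth.json")
    assign = pd.read_csv(MODULES / "module_assignment.tsv", sep="\t", index_col=0)
    true_labels = np.array([truth.module_labels.get(g, 0) for g in assign.index])
    ari = adjusted_rand_score(true_labels, assign["module"].to_numpy())

    tc = pd.read_csv(MODULES / "module_trait_cor.tsv", sep="\t")
    hits = total = 0
    for mid, shifts in truth.group_shifts.items():
        planted = {g for g, m in truth.module_labels.items() if m == mid}
        overlap = assign.loc[assign.index.isin(planted), "module"]
        best = overlap[overlap > 0].mode()
        if best.empty:
            continue
        row = tc[(tc["module"] == f"M{best.iloc[0]}") & (tc["trait"] == "stage")]
        total += 1
        planted_dir = truth.module_signs[mid] * np.sign(shifts[2] - shifts[0])
        hits += int(np.sign(row["cor"].iloc[0]) == planted_dir)

    pres = pd.read_csv(STATS / "preservation.tsv", sep="\t")
    diff = pd.read_csv(DIFF / "differential_edges.tsv", sep="\t")
    perturbed = {g for p in truth.perturbed_edges for g in p.edge}
    ad_calls = diff[(diff["contrast"] == "young_vs_ad") & diff["passes"]]
    flagged_genes = set(ad_calls["source"]) | set(ad_calls["target"])

    rows = {
        "module_ari": round(ari, 4),
        "stage_sign_accuracy": hits / total if total else float("nan"),
        "preservation_min_zsummary": pres["z_summary"].min().round(2),
        "n_differential_edges_young_vs_ad": len(ad_calls),
        "perturbed_genes_flagged": len(perturbed & flagged_genes),
        "n_perturbed_genes": len(perturbed),
    }
    pd.Series(rows).to_csv("results/benchmark_summary.tsv", sep="\t", header=False)
    for k, v in rows.items():
        print(f"{k:40s} {v}")


if __name__ == "__main__":
    main()
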