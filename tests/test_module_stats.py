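"""Moderated t, DEG filtering, Fisher overlap and Zsummary preservation."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from netage import reference
from netage.expression_io import ExpressionDataset
from netage.module_stats import (
    ModuleStatsError,
    deg_filter,
    fisher_overlap,
    moderated_ttest,
    module_preservation,
    overlap_table,
)
from netage.synthetic import ModuleSpec, SyntheticSpec, generate_expression


def _two_group_dataset(rng, n_genes=200, n_per_group=8, delta=None, sd=0.5):
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    X = rng.normal(8.0, sd, size=(n_genes, 2 * n_per_group))
    if delta is not None:
        X[: len(delta), n_per_group:] += np.asarray(delta)[:, None]
    meta = pd.DataFrame(
        {
            "group": ["young"] * n_per_group + ["aging"] * n_per_group,
            "age": 50.0,
            "sex": "F",
        },
        index=samples,
    )
    return ExpressionDataset(
        pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=samples), meta
    )


def test_gene_with_equal_group_means_gets_t_zero_p_one():
    rng = np.random.default_rng(0)
    ds = _two_group_dataset(rng)
    X = ds.matrix.to_numpy()
    X[0, 8:] = X[0, :8]  # identical values in both groups
    table = moderated_ttest(ds, "young", "aging")
    assert table.loc["g0", "t"] == 0.0
    assert table.loc["g0", "p"] == 1.0


def test_infinite_prior_df_recovers_z_statistic_at_prior_variance():
    rng = np.random.default_rng(1)
    ds = _two_group_dataset(rng)
    s0 = 0.3
    table = moderated_ttest(ds, "young", "aging", prior_df=np.inf, prior_var=s0)
    lfc = ds.matrix.iloc[:, 8:].mean(axis=1) - ds.matrix.iloc[:, :8].mean(axis=1)
    expected = lfc / np.sqrt(s0 * (1 / 8 + 1 / 8))
    assert np.allclose(table["t"], expected)


def test_bh_adjustment_is_monotone_step_up():
    rng = np.random.default_rng(2)
    ds = _two_group_dataset(rng)
    table = moderated_ttest(ds, "young", "aging").sort_values("p")
    assert (table["adj_p"].to_numpy() >= table["p"].to_numpy() - 1e-15).all()
    assert (np.diff(table.sort_values("p")["adj_p"].cummax()) >= -1e-15).all()


def test_moderated_t_agrees_with_limma():
    """Independent cross-check of the empirical-Bayes machinery against the
    Bioconductor implementation on one simulated two-group dataset."""
    rng = np.random.default_rng(3)
    delta = np.concatenate([np.full(10, 1.0), np.zeros(0)])
    ds = _two_group_dataset(rng, n_genes=120, n_per_group=8, delta=delta)
    table = moderated_ttest(ds, "young", "aging")
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        expr = os.path.join(td, "expr.csv")
        out = os.path.join(td, "limma.csv")
        ds.matrix.to_csv(expr)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{expr}", row.names = 1))
            group <- factor(rep(c("a", "b"), each = 8), levels = c("a", "b"))
            design <- model.matrix(~ group)
            fit <- eBayes(lmFit(x, design))
            write.csv(data.frame(t = fit$t[, 2], p = fit$p.value[, 2]), "{out}")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        limma = pd.read_csv(out, index_col=0)
    r = np.corrcoef(table["t"].to_numpy(), limma["t"].to_numpy())[0, 1]
    assert r > 0.999
    # shrinkage targets agree closely, so the statistics do too
    assert np.abs(table["t"].to_numpy() - limma["t"].to_numpy()).max() < 0.2


def test_deg_filter_applies_fold_change_and_fdr_jointly():
    table = pd.DataFrame(
        {
            "log2fc": [np.log2(1.6), np.log2(1.6), -np.log2(1.6), 0.1],
            "adj_p": [0.01, 0.20, 0.01, 0.01],
        },
        index=["up_sig", "up_notsig", "down_sig", "small_fc"],
    )
    up, down = deg_filter(table, fc_threshold=1.5, fdr=0.05)
    assert up == ["up_sig"]
    assert down == ["down_sig"]


def test_deg_filter_recovers_planted_two_fold_shift():
    rng = np.random.default_rng(4)
    delta = np.full(50, 1.0)  # 2-fold on the log2 scale, small residual noise
    ds = _two_group_dataset(rng, n_genes=1000, n_per_group=10, delta=delta, sd=0.25)
    table = moderated_ttest(ds, "young", "aging")
    up, down = deg_filter(table)
    planted = {f"g{i}" for i in range(50)}
    called = set(up) | set(down)
    recall = len(set(up) & planted) / 50
    false_calls = len(called - planted)
    assert recall >= 0.9
    assert false_calls <= max(1, 0.05 * len(called))


def test_fisher_identical_sets_give_minimal_tail_probability():
    universe = [f"g{i}" for i in range(100)]
    module = universe[:10]
    res = fisher_overlap(module, module, universe)
    from math import comb

    assert res.p == pytest.approx(1 / comb(100, 10), rel=1e-9)


def test_fisher_empty_intersection_gives_p_one():
    universe = [f"g{i}" for i in range(40)]
    res = fisher_overlap(universe[:10], universe[10:20], universe)
    assert res.p == pytest.approx(1.0)


def test_fisher_overlap_at_expectation_is_not_enriched():
    # 20-gene module, 20-gene set in a 100-gene universe: expected overlap 4
    universe = [f"g{i}" for i in range(100)]
    module = universe[:20]
    markers = universe[16:36]  # intersection exactly 4
    res = fisher_overlap(module, markers, universe)
    assert res.intersection == 4
    assert res.p >= 0.5


def test_fisher_matches_exact_tail_on_small_tables():
    universe = [f"g{i}" for i in range(8)]
    for n_set in range(0, 9):
        for n_mod in range(0, 9):
            for k in range(max(0, n_set + n_mod - 8), min(n_set, n_mod) + 1):
                module = universe[:k] + universe[n_set : n_set + n_mod - k]
                if len(module) != n_mod:
                    continue
                res = fisher_overlap(module, universe[:n_set], universe)
                exact = reference.hypergeom_tail_reference(k, 8, n_set, n_mod)
                assert res.p == pytest.approx(exact, abs=1e-12)


def test_overlap_table_covers_all_pairs():
    universe = [f"g{i}" for i in range(30)]
    table = overlap_table(
        {1: universe[:10], 2: universe[10:20]},
        {"astro": universe[:5], "neuron": universe[25:]},
        universe,
    )
    assert len(table) == 4
    assert table.loc[
        (table["module_id"] == 1) & (table["set_name"] == "astro"), "intersection"
    ].iloc[0] == 5


def _preservation_pair(seed, test_kind):
    spec = SyntheticSpec(
        n_genes=400,
        n_samples_per_group=(17, 21, 18),
        modules=(ModuleSpec(80, 0.8, (0.0, 1.0, 2.0)),),
        noise_sd=1.0,
        seed=seed,
    )
    ref, truth = generate_expression(spec)
    if test_kind == "replicate":
        test, _ = generate_expression(
            SyntheticSpec(**{**vars(spec), "seed": seed + 1000})
        )
    else:
        test, _ = generate_expression(
            SyntheticSpec(
                n_genes=400,
                n_samples_per_group=(17, 21, 18),
                modules=(),
                noise_sd=1.0,
                seed=seed + 2000,
            )
        )
    return ref, pd.Series(truth.module_labels), test


def test_preserved_module_scores_strong_in_replicate():
    ref, labels, test = _preservation_pair(0, "replicate")
    (res,) = module_preservation(ref, labels, test, power=6, n_perm=100, seed=0)
    assert res.z_summary > 10
    assert res.preservation_class == "strong"


def test_random_gene_set_is_not_preserved():
    ref, labels, test = _preservation_pair(0, "replicate")
    rng = np.random.default_rng(5)
    shuffled = pd.Series(
        rng.permutation(labels.to_numpy()), index=labels.index
    )
    (res,) = module_preservation(ref, shuffled, test, power=6, n_perm=100, seed=0)
    assert res.z_summary < 2


def test_preservation_z_increases_with_module_strength():
    means = []
    for r in (0.4, 0.6, 0.8):
        zs = []
        for seed in range(3):
            spec = SyntheticSpec(
                n_genes=300,
                n_samples_per_group=(17, 21, 18),
                modules=(ModuleSpec(60, r, (0.0, 1.0, 2.0)),),
                noise_sd=1.0,
                seed=seed,
            )
            ref, truth = generate_expression(spec)
            test, _ = generate_expression(
                SyntheticSpec(**{**vars(spec), "seed": seed + 1000})
            )
            (res,) = module_preservation(
                ref, pd.Series(truth.module_labels), test, power=6, n_perm=50, seed=seed
            )
            zs.append(res.z_summary)
        means.append(np.mean(zs))
    assert means[0] < means[1] < means[2]


def test_preservation_rejects_tiny_intersection():
    ref, labels, test = _preservation_pair(1, "replicate")
    small = labels.copy()
    small[:] = 0
    small.iloc[:5] = 1
    with pytest.raises(ModuleStatsError, match="after intersection"):
        module_preservation(ref, small, test, power=6, n_perm=10, seed=0)
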