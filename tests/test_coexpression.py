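"""Signed network construction, power selection, TOM, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from netage import reference
from netage.coexpression import (
    CoexpressionError,
    ScaleFreeFit,
    adjacency,
    cluster_modules,
    intramodular_connectivity,
    intramodular_hubs,
    module_eigengenes,
    module_trait_correlation,
    scale_free_fit,
    scale_free_fit_index,
    select_power,
    signed_similarity,
    topological_overlap,
)
from netage.expression_io import ExpressionDataset, TraitEncoding
from netage.synthetic import ModuleSpec, SyntheticSpec, generate_expression


def _dataset(matrix: np.ndarray) -> ExpressionDataset:
    samples = [f"s{i}" for i in range(matrix.shape[1])]
    meta = pd.DataFrame(
        {"group": ["young"] * len(samples), "age": 30.0, "sex": "F"}, index=samples
    )
    return ExpressionDataset(
        pd.DataFrame(matrix, index=[f"g{i}" for i in range(matrix.shape[0])], columns=samples),
        meta,
    )


def test_signed_similarity_maps_correlation_endpoints():
    t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    X = np.vstack([np.sin(t), 2 * np.sin(t) + 1, -np.sin(t), np.cos(t)])
    S = signed_similarity(_dataset(X))
    assert S.loc["g0", "g1"] == pytest.approx(1.0)   # cor = +1
    assert S.loc["g0", "g2"] == pytest.approx(0.0)   # cor = -1
    assert S.loc["g0", "g3"] == pytest.approx(0.5, abs=1e-12)  # cor = 0


def test_signed_similarity_range_and_diagonal():
    rng = np.random.default_rng(0)
    S = signed_similarity(_dataset(rng.normal(size=(30, 15)))).to_numpy()
    assert np.all(S >= 0) and np.all(S <= 1)
    assert np.allclose(np.diag(S), 1.0)
    assert np.allclose(S, S.T)


def test_signed_similarity_rejects_constant_gene():
    X = np.random.default_rng(0).normal(size=(3, 8))
    X[1] = 4.2
    with pytest.raises(CoexpressionError, match="g1"):
        signed_similarity(_dataset(X))


def test_scale_free_index_rewards_power_law_degrees():
    # degrees k_i proportional to 1/i follow an exact power law
    k = 1000.0 / np.arange(1, 301)
    r2, slope, _ = scale_free_fit_index(k, n_bins=10)
    assert r2 >= 0.9
    assert slope < 0


def test_scale_free_index_flags_degenerate_degrees():
    r2, _, n_bins = scale_free_fit_index(np.full(50, 3.0))
    assert np.isnan(r2)
    assert n_bins == 1


def test_mean_connectivity_strictly_decreases_with_power():
    rng = np.random.default_rng(1)
    S = signed_similarity(_dataset(rng.normal(size=(40, 20))))
    fit = scale_free_fit(S, powers=range(1, 15))
    mean_k = fit.table["mean_k"].to_numpy()
    assert np.all(np.diff(mean_k) < 0)


@pytest.mark.parametrize(
    "records,expected,fallback",
    [
        ([(6, 0.5), (12, 0.82), (18, 0.85)], 12, False),
        ([(6, 0.82)], 6, False),
    ],
)
def test_select_power_lowest_reaching_threshold(records, expected, fallback):
    table = pd.DataFrame(
        [{"power": p, "r_squared": r, "valid": True} for p, r in records]
    )
    power, fb = select_power(ScaleFreeFit(table))
    assert power == expected
    assert fb is fallback


def test_select_power_falls_back_to_saturation_knee():
    table = pd.DataFrame(
        [
            {"power": p, "r_squared": r, "valid": True}
            for p, r in [(6, 0.30), (12, 0.55), (18, 0.60), (24, 0.602)]
        ]
    )
    power, fb = select_power(ScaleFreeFit(table))
    assert fb is True
    assert power == 18  # first gain below 0.01 over the previous power


def test_tom_hand_computed_triangle():
    A = np.ones((3, 3)) - np.eye(3)
    tom = topological_overlap(A)
    # TOM_12 = (1 + 1) / (min(2,2) + 1 - 1) = 1
    assert np.allclose(tom, 1.0)


def test_tom_empty_network_has_zero_overlap():
    tom = topological_overlap(np.zeros((3, 3)))
    assert np.allclose(tom - np.eye(3), 0.0)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(5)
    raw = rng.uniform(0, 1, size=(10, 10))
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 0)
    assert np.abs(topological_overlap(A) - reference.tom_reference(A)).max() < 1e-12


def test_two_planted_blocks_recovered_exactly(two_block_data):
    from sklearn.metrics import adjusted_rand_score

    ds, truth = two_block_data
    S = signed_similarity(ds)
    tom = topological_overlap(adjacency(S, 6))
    modules = cluster_modules(tom, ds.genes, min_module_size=150)
    true_labels = [truth.module_labels[g] for g in ds.genes]
    assert len(modules.module_ids) == 2
    assert adjusted_rand_score(true_labels, modules.labels) >= 0.95


def test_pure_noise_leaves_genes_unassigned():
    spec = SyntheticSpec(
        n_genes=800, n_samples_per_group=(17, 21, 18), modules=(), noise_sd=1.0, seed=4
    )
    ds, _ = generate_expression(spec)
    S = signed_similarity(ds)
    tom = topological_overlap(adjacency(S, 6))
    modules = cluster_modules(tom, ds.genes, min_module_size=150)
    assert (modules.labels == 0).mean() >= 0.9


def test_block_below_minimum_size_yields_no_modules():
    spec = SyntheticSpec(
        n_genes=400,
        n_samples_per_group=(17, 21, 18),
        modules=(ModuleSpec(100, 0.8, (0, 1, 2)),),
        noise_sd=1.0,
        seed=4,
    )
    ds, _ = generate_expression(spec)
    S = signed_similarity(ds)
    tom = topological_overlap(adjacency(S, 6))
    modules = cluster_modules(tom, ds.genes, min_module_size=150)
    assert modules.module_ids == []


def test_eigengene_of_identical_profiles_is_the_common_profile():
    rng = np.random.default_rng(2)
    profile = rng.normal(size=15)
    X = np.tile(profile, (5, 1))
    ds = _dataset(X)
    labels = pd.Series(1, index=ds.genes)
    me = module_eigengenes(ds, labels).loc["M1"].to_numpy()
    standardized = (profile - profile.mean()) / profile.std()
    assert np.allclose(me, standardized, atol=1e-8)


def test_eigengene_recovers_planted_latent_up_to_sign_flips():
    spec = SyntheticSpec(
        n_genes=120,
        n_samples_per_group=(17, 21, 18),
        modules=(ModuleSpec(60, 0.8, (0, 1, 2)),),
        noise_sd=1.0,
        seed=9,
    )
    ds, truth = generate_expression(spec)
    labels = pd.Series(truth.module_labels)
    me = module_eigengenes(ds, labels).loc["M1"].to_numpy()
    latent = truth.latents.loc[1].to_numpy()
    assert abs(np.corrcoef(me, latent)[0, 1]) >= 0.95

    flipped = ExpressionDataset(-ds.matrix, ds.sample_meta)
    me_f = module_eigengenes(flipped, labels).loc["M1"].to_numpy()
    assert abs(np.corrcoef(me_f, latent)[0, 1]) == pytest.approx(
        abs(np.corrcoef(me, latent)[0, 1]), abs=1e-9
    )


def test_trait_correlation_of_stage_with_itself(tiny_dataset):
    traits = TraitEncoding.from_dataset(tiny_dataset)
    me = pd.DataFrame([traits.stage.to_numpy()], index=["M1"], columns=tiny_dataset.samples)
    table = module_trait_correlation(me, traits)
    row = table[(table["module"] == "M1") & (table["trait"] == "stage")].iloc[0]
    assert row["cor"] == pytest.approx(1.0)
    assert row["p"] < 1e-10


def test_trait_correlation_zero_for_orthogonal_eigengene(tiny_dataset):
    traits = TraitEncoding.from_dataset(tiny_dataset)
    stage = traits.stage.to_numpy()
    v = np.zeros_like(stage, dtype=float)
    v[: len(v) // 2], v[len(v) // 2 :] = 1.0, -1.0
    v -= v.mean()
    v -= stage.std() and (v @ (stage - stage.mean())) / ((stage - stage.mean()) @ (stage - stage.mean())) * (stage - stage.mean())
    me = pd.DataFrame([v], index=["M1"], columns=tiny_dataset.samples)
    table = module_trait_correlation(me, traits)
    row = table[(table["module"] == "M1") & (table["trait"] == "stage")].iloc[0]
    assert row["cor"] == pytest.approx(0.0, abs=1e-10)


def test_stage_correlation_power_for_planted_shift():
    """A one-SD monotone eigengene shift is detected in >= 90% of replicates."""
    detected = 0
    n_rep = 60
    for seed in range(n_rep):
        spec = SyntheticSpec(
            n_genes=40,
            n_samples_per_group=(17, 21, 18),
            modules=(ModuleSpec(30, 0.7, (0.0, 1.0, 2.0)),),
            noise_sd=1.0,
            seed=seed,
        )
        ds, truth = generate_expression(spec)
        labels = pd.Series(truth.module_labels)
        me = module_eigengenes(ds, labels)
        traits = TraitEncoding.from_dataset(ds)
        table = module_trait_correlation(me, traits)
        row = table[(table["module"] == "M1") & (table["trait"] == "stage")].iloc[0]
        if row["p"] < 0.05 and row["cor"] > 0:
            detected += 1
    assert detected / n_rep >= 0.9


def test_star_module_center_is_top_hub():
    rng = np.random.default_rng(3)
    center = rng.normal(size=30)
    X = np.vstack(
        [center]
        + [0.9 * center + 0.45 * rng.normal(size=30) for _ in range(6)]
    )
    ds = _dataset(X)
    S = signed_similarity(ds)
    A = adjacency(S, 6)
    labels = pd.Series(1, index=ds.genes)
    hubs = intramodular_hubs(A, ds.genes, labels, top_n=3)
    assert hubs[1].iloc[0]["gene"] == "g0"


def test_two_gene_module_has_symmetric_kim():
    rng = np.random.default_rng(4)
    ds = _dataset(rng.normal(size=(2, 12)))
    S = signed_similarity(ds)
    A = adjacency(S, 6)
    kim = intramodular_connectivity(A, ds.genes, pd.Series(1, index=ds.genes))
    assert kim["g0"] == pytest.approx(kim["g1"])
    assert kim["g0"] <= 1.0  # kim bounded by module size - 1
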