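"""Differential expression, cell-type overlap and module preservation.

Differential expression uses empirical-Bayes moderated t-statistics: per-gene
residual variances are shrunk toward a common prior estimated by
moment-matching the scaled-F distribution of the sample variances, which
stabilises tests at small n.  Module / marker-list overlap is the one-sided
Fisher exact (hypergeometric tail) test.  Module preservation asks whether a
module found in a reference dataset keeps its density and connectivity
pattern in an independent test dataset, summarised as a permutation Z
(Zsummary < 2: no preservation, 2-10: weak to moderate, > 10: strong).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .coexpression import adjacency, signed_similarity
from .expression_io import ExpressionDataset


class ModuleStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Moderated t / DEGs
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from sample variances.

    Moment-matching on the log scale: if s_g^2 ~ s0^2 * F(df, d0), then
    z = log s_g^2 has mean log s0^2 + digamma(df/2) - log(df/2)
    - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2) beyond
    trigamma(df/2).  Returns (d0, s0_squared); d0 = inf when the empirical
    spread does not exceed the chi-square expectation.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by Newton iteration (monotone decreasing)
    y = 0.5 + 1.0 / e_var  # starting value from the 1/x asymptote
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / e_var) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_ttest(
    dataset: ExpressionDataset,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test per gene.

    The pooled residual variance s_g^2 (d_g = n_a + n_b - 2 df) is shrunk to
    the posterior (d0*s0^2 + d_g*s_g^2)/(d0 + d_g); the moderated t uses
    d0 + d_g degrees of freedom.  Fold changes are reported as the difference
    of group means on the log2 scale (group_b minus group_a).  *prior_df* /
    *prior_var* override the moment-matched estimates (``prior_df=inf``
    recovers a z-like test at the prior variance).
    """
    a_cols = dataset.group_samples(group_a)
    b_cols = dataset.group_samples(group_b)
    n_a, n_b = len(a_cols), len(b_cols)
    if n_a < 2 or n_b < 2:
        raise ModuleStatsError(
            f"need >= 2 samples per group; got {group_a}:{n_a}, {group_b}:{n_b}"
        )
    Xa = dataset.matrix[a_cols].to_numpy(dtype=float)
    Xb = dataset.matrix[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    lfc = mean_b - mean_a
    df_resid = n_a + n_b - 2
    if df_resid <= 0:
        raise ModuleStatsError("zero residual degrees of freedom")
    ss = Xa.var(axis=1, ddof=1) * (n_a - 1) + Xb.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df_resid

    if prior_df is None or prior_var is None:
        d0_est, s0_est = _fit_f_dist(s2, df_resid)
        d0 = d0_est if prior_df is None else prior_df
        s0_sq = s0_est if prior_var is None else prior_var
    else:
        d0, s0_sq = prior_df, prior_var

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    tstat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2 * stats.t.sf(np.abs(tstat), df=df_total)
    p = np.where((lfc == 0), 1.0, p)
    adj_p = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": dataset.genes,
            "contrast": f"{group_a}_vs_{group_b}",
            "log2fc": lfc,
            "t": tstat,
            "p": p,
            "adj_p": adj_p,
            "prior_df": d0,
            "prior_var": s0_sq,
        }
    ).set_index("gene")


def deg_filter(
    table: pd.DataFrame, fc_threshold: float = 1.5, fdr: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split a moderated-t table into up/down DEG lists.

    A gene is up when its linear fold change 2**log2fc >= fc_threshold and
    adjusted p < fdr; down when 2**log2fc <= 1/fc_threshold at the same FDR.
    """
    if table.empty:
        raise ModuleStatsError("empty DEG table")
    fc = np.power(2.0, table["log2fc"])
    sig = table["adj_p"] < fdr
    up = sorted(table.index[sig & (fc >= fc_threshold)])
    down = sorted(table.index[sig & (fc <= 1.0 / fc_threshold)])
    return up, down


# ---------------------------------------------------------------------------
# Fisher / hypergeometric overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    module_id: int | str
    set_name: str
    module_size: int
    set_size: int
    intersection: int
    universe: int
    p: float
    odds_ratio: float


def fisher_overlap(
    module_genes: Sequence[str],
    marker_genes: Sequence[str],
    universe: Sequence[str],
    module_id: int | str = "",
    set_name: str = "",
) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test for module / gene-set overlap.

    The p-value is the upper hypergeometric tail P(X >= observed overlap)
    with the 2x2 margins taken over *universe*.
    """
    uni = set(universe)
    if not uni:
        raise ModuleStatsError("empty universe")
    mod = set(module_genes) & uni
    mark = set(marker_genes) & uni
    if set(module_genes) - uni or set(marker_genes) - uni:
        raise ModuleStatsError("module/marker genes outside the universe")
    n = len(uni)
    k = len(mod & mark)
    p = float(stats.hypergeom.sf(k - 1, n, len(mark), len(mod)))
    a, b = k, len(mod) - k
    c, d = len(mark) - k, n - len(mod) - len(mark) + k
    odds = float(a * d / (b * c)) if b * c > 0 else float("inf")
    return OverlapResult(
        module_id=module_id,
        set_name=set_name,
        module_size=len(mod),
        set_size=len(mark),
        intersection=k,
        universe=n,
        p=min(p, 1.0),
        odds_ratio=odds,
    )


def overlap_table(
    modules: Mapping[int, Sequence[str]],
    marker_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """All module x marker-set overlap tests as one tidy frame."""
    rows = []
    for mid, genes in modules.items():
        for name, markers in marker_sets.items():
            markers_in = [g for g in markers if g in set(universe)]
            res = fisher_overlap(genes, markers_in, universe, mid, name)
            rows.append(vars(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Module preservation (Zsummary)
# ---------------------------------------------------------------------------

@dataclass
class PreservationResult:
    module_id: int
    z_density: float
    z_connectivity: float
    z_summary: float
    n_genes_used: int
    n_permutations: int

    @property
    def preservation_class(self) -> str:
        if self.z_summary > 10:
            return "strong"
        if self.z_summary >= 2:
            return "weak-moderate"
        return "none"


def _module_stats_in(
    ref_X: np.ndarray, test_X: np.ndarray, power: int
) -> tuple[float, float]:
    """(density, kIM-rank correlation ref vs test) for one gene set."""
    A_test = _signed_adjacency(test_X, power)
    m = A_test.shape[0]
    density = float(A_test.sum() / (m * (m - 1)))
    A_ref = _signed_adjacency(ref_X, power)
    k_ref = A_ref.sum(axis=1)
    k_test = A_test.sum(axis=1)
    conn = float(stats.spearmanr(k_ref, k_test).statistic)
    return density, conn


def _signed_adjacency(X: np.ndarray, power: int) -> np.ndarray:
    sd = X.std(axis=1)
    X = X + 0.0
    # guard: constant rows get an exact-zero correlation rather than NaN
    if np.any(sd == 0):
        X = X + 1e-9 * np.random.default_rng(0).normal(size=X.shape)
    cor = np.corrcoef(X)
    A = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(A, 0.0)
    return A


def module_preservation(
    reference: ExpressionDataset,
    labels: pd.Series,
    test: ExpressionDataset,
    power: int = 6,
    n_perm: int = 100,
    seed: int = 0,
    min_overlap_frac: float = 0.5,
    min_genes: int = 10,
) -> list[PreservationResult]:
    """Permutation Zsummary preservation of reference modules in a test dataset.

    For each module, the observed statistics in the test data are the mean
    off-diagonal signed adjacency (density) and the rank correlation between
    reference and test intramodular connectivities (connectivity).  The null
    is built from *n_perm* random gene sets of the same size drawn from the
    test dataset's genes; Z = (obs - mean_null) / sd_null for each statistic
    and Zsummary is their mean.
    """
    rng = np.random.default_rng(seed)
    common = [g for g in reference.genes if g in set(test.genes)]
    common_set = set(common)
    results = []
    test_common = test.matrix.loc[common]
    ref_common = reference.matrix.loc[common]
    gene_pos = {g: i for i, g in enumerate(common)}
    test_arr = test_common.to_numpy(dtype=float)
    ref_arr = ref_common.to_numpy(dtype=float)

    for mid in sorted(set(labels) - {0}):
        module_genes = list(labels.index[labels == mid])
        present = [g for g in module_genes if g in common_set]
        if len(present) < min_overlap_frac * len(module_genes):
            import warnings

            warnings.warn(
                f"module {mid}: only {len(present)}/{len(module_genes)} genes in test data"
            )
        if len(present) < min_genes:
            raise ModuleStatsError(
                f"module {mid} has {len(present)} genes after intersection (< {min_genes})"
            )
        rows = [gene_pos[g] for g in present]
        obs_d, obs_c = _module_stats_in(ref_arr[rows], test_arr[rows], power)

        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for i in range(n_perm):
            perm_rows = rng.choice(len(common), size=len(present), replace=False)
            null_d[i], null_c[i] = _module_stats_in(
                ref_arr[perm_rows], test_arr[perm_rows], power
            )
        z_d = _z(obs_d, null_d)
        z_c = _z(obs_c, null_c)
        results.append(
            PreservationResult(
                module_id=mid,
                z_density=z_d,
                z_connectivity=z_c,
                z_summary=(z_d + z_c) / 2.0,
                n_genes_used=len(present),
                n_permutations=n_perm,
            )
        )
    return results


def _z(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd == 0:
        return 0.0 if obs == null.mean() else float("inf") * np.sign(obs - null.mean())
    return float((obs - null.mean()) / sd)


def preservation_frame(results: Sequence[PreservationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module_id,
                "z_density": r.z_density,
                "z_connectivity": r.z_connectivity,
                "z_summary": r.z_summary,
                "class": r.preservation_class,
                "n_genes": r.n_genes_used,
                "n_perm": r.n_permutations,
            }
            for r in results
        ]
    )
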