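"""Signed weighted co-expression network construction and module detection.

The signed similarity maps Pearson correlation onto [0, 1],

    S_ij = (1 + cor(x_i, x_j)) / 2,

so anti-correlated genes land near 0 instead of being folded onto positive
correlation.  Raising S elementwise to a soft-threshold power beta gives the
weighted adjacency a_ij = S_ij**beta; beta is chosen as the lowest power at
which the network's degree distribution approximately follows a power law
(the scale-free topology criterion).  The adjacency is transformed into the
topological overlap matrix (TOM), which rewards shared neighbourhoods, and
1 - TOM is the distance for average-linkage clustering.  The dendrogram is cut
into branches; branches above a minimum size become modules.  Each module is
summarised by its eigengene (first singular vector of the standardized member
expression), correlated against sample traits, and ranked internally by
intramodular connectivity to nominate hub genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_io import ExpressionDataset, TraitEncoding

DEFAULT_POWERS = tuple(range(1, 31))


class CoexpressionError(ValueError):
    pass


def signed_similarity(dataset: ExpressionDataset) -> pd.DataFrame:
    """Signed similarity S = (1 + Pearson correlation) / 2, in [0, 1]."""
    X = dataset.matrix.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise CoexpressionError("need at least 3 samples for correlation")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = dataset.genes[sd == 0].tolist()
        raise CoexpressionError(
            f"constant-expression genes make correlation undefined: {bad[:5]} "
            "(apply iqr_filter first)"
        )
    cor = np.corrcoef(X)
    S = (1.0 + cor) / 2.0
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=dataset.genes, columns=dataset.genes)


def adjacency(similarity: pd.DataFrame | np.ndarray, power: int) -> np.ndarray:
    A = np.asarray(similarity, dtype=float) ** power
    np.fill_diagonal(A, 0.0)  # self-adjacency excluded from connectivity
    return A


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene connectivity k: row sums of the adjacency (self excluded)."""
    return adj.sum(axis=1)


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit across candidate soft-threshold powers."""

    table: pd.DataFrame  # columns: power, r_squared, slope, mean_k, median_k, max_k, valid

    def record(self, power: int) -> pd.Series:
        return self.table.set_index("power").loc[power]


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, int]:
    """Signed R^2 of log10 p(k) vs log10 k on equal-width connectivity bins.

    Returns (signed r_squared, slope, n_nonempty_bins); r_squared is NaN when
    fewer than 3 bins are occupied (degenerate degree distribution).
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return float("nan"), float("nan"), 1
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        centers.append(members.mean())
        freqs.append(members.size / k.size)
    if len(centers) < 3:
        return float("nan"), float("nan"), len(centers)
    lx = np.log10(np.asarray(centers))
    ly = np.log10(np.asarray(freqs))
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2), float(slope), len(centers)


def scale_free_fit(
    similarity: pd.DataFrame | np.ndarray,
    powers: Sequence[int] = DEFAULT_POWERS,
    n_bins: int = 10,
) -> ScaleFreeFit:
    """Evaluate the scale-free criterion for each candidate power."""
    if min(powers) < 1:
        raise CoexpressionError("powers must be >= 1")
    if n_bins < 4:
        raise CoexpressionError("n_bins must be >= 4")
    S = np.asarray(similarity, dtype=float)
    rows = []
    for beta in powers:
        k = connectivity(adjacency(S, beta))
        r2, slope, nb = scale_free_fit_index(k, n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "r_squared": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
                "valid": nb >= 3,
            }
        )
    return ScaleFreeFit(pd.DataFrame(rows))


def select_power(
    fit: ScaleFreeFit, r2_threshold: float = 0.8, knee_gain: float = 0.01
) -> tuple[int, bool]:
    """Lowest power reaching the R^2 threshold, else the saturation knee.

    Returns ``(power, fallback)`` where ``fallback`` is True when no power
    reached the threshold; in that case the power where the fit curve
    saturates is returned — the lowest power whose R^2 is within *knee_gain*
    of the curve's plateau (its maximum over the grid), which is robust to
    the non-monotone wiggles empirical fit curves show.
    """
    tab = fit.table[fit.table["valid"]].reset_index(drop=True)
    if tab.empty:
        raise CoexpressionError("no valid scale-free fit records")
    reaching = tab[tab["r_squared"] >= r2_threshold]
    if not reaching.empty:
        return int(reaching.iloc[0]["power"]), False
    plateau = tab["r_squared"].max()
    chosen = tab[tab["r_squared"] >= plateau - knee_gain].iloc[0]
    return int(chosen["power"]), True


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    The diagonal is set to 1 by convention.  Input must be symmetric with
    entries in [0, 1]; the diagonal is zeroed internally.
    """
    A = np.array(adj, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise CoexpressionError("adjacency must be symmetric")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    tom = (tom + tom.T) / 2.0  # symmetrize away floating-point asymmetry
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleSet:
    """Module labels plus the summaries built on top of them.

    Labels map every gene to a module ID; 0 is the unassigned ("grey") label.
    Modules are numbered by decreasing size.
    """

    labels: pd.Series                      # gene -> module id
    linkage_matrix: np.ndarray | None = None
    cut_height: float | None = None
    eigengenes: pd.DataFrame | None = None  # module x sample
    kim: pd.Series | None = None
    trait_cor: pd.DataFrame | None = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def module_genes(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}


def cluster_modules(
    tom: np.ndarray,
    genes: Sequence[str],
    min_module_size: int = 150,
    method: str = "branch",
    gap_factor: float = 10.0,
    min_relative_gap: float = 0.1,
    cut_quantile: float = 0.99,
) -> ModuleSet:
    """Cut the average-linkage dendrogram of 1 - TOM into modules.

    ``method="branch"`` (default) selects long-lived branches: an internal
    node of the tree with at least *min_module_size* leaves is a module
    candidate when its lifetime (its parent's merge height minus its own)
    exceeds *gap_factor* times the median lifetime of all such nodes — a
    genuine module sits on its own branch well below the height at which it
    joins the rest of the tree, while background genes merge in a near-
    continuous chain.  A candidate must additionally be separated from its
    surroundings by a gap comparable to its own cohesion margin,
    lifetime / (1 - height) >= *min_relative_gap*, which rejects weakly
    attached aggregates of sub-threshold blocks plus chained background.
    Candidates are accepted in decreasing lifetime order, skipping any that
    overlap an accepted branch.

    ``method="static"`` instead cuts the whole tree at the *cut_quantile* of
    its merge heights and keeps clusters of at least *min_module_size*.

    Modules are numbered by decreasing size; all other genes get label 0.
    """
    genes = list(genes)
    n = len(genes)
    if min_module_size < 2:
        raise CoexpressionError("min_module_size must be >= 2")
    if n < min_module_size:
        import warnings

        warnings.warn(
            f"{n} genes < min_module_size={min_module_size}; all genes unassigned"
        )
        return ModuleSet(labels=pd.Series(0, index=pd.Index(genes, name="gene")))
    dist = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")

    if method == "static":
        cut = float(np.quantile(Z[:, 2], cut_quantile))
        raw = fcluster(Z, t=cut, criterion="distance")
        sizes = pd.Series(raw).value_counts()
        big = sizes[sizes >= min_module_size]
        order = sorted(big.index, key=lambda c: (-big[c], c))
        relabel = {c: i + 1 for i, c in enumerate(order)}
        labels = pd.Series(
            [relabel.get(c, 0) for c in raw], index=pd.Index(genes, name="gene")
        )
        return ModuleSet(labels=labels, linkage_matrix=Z, cut_height=cut)
    if method != "branch":
        raise CoexpressionError(f"unknown clustering method {method!r}")

    members: list[list[int] | None] = [[i] for i in range(n)] + [None] * (n - 1)
    heights = np.zeros(2 * n - 1)
    parent_h = np.full(2 * n - 1, np.nan)
    for k in range(n - 1):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        node = n + k
        members[node] = members[a] + members[b]  # type: ignore[operator]
        heights[node] = Z[k, 2]
        parent_h[a] = parent_h[b] = Z[k, 2]
    root = 2 * n - 2
    big_nodes = [
        nd
        for nd in range(n, 2 * n - 1)
        if nd != root and len(members[nd]) >= min_module_size  # type: ignore[arg-type]
    ]
    raw_labels = np.zeros(n, dtype=int)
    if big_nodes:
        lifetime = {nd: float(parent_h[nd] - heights[nd]) for nd in big_nodes}
        tau = gap_factor * max(float(np.median(list(lifetime.values()))), 1e-12)
        candidates = sorted(
            (
                nd
                for nd in big_nodes
                if lifetime[nd] >= tau
                and lifetime[nd] >= min_relative_gap * max(1.0 - heights[nd], 1e-12)
            ),
            key=lambda nd: -lifetime[nd],
        )
        taken = np.zeros(n, dtype=bool)
        chosen: list[int] = []
        for nd in candidates:
            idx = np.array(members[nd])
            if taken[idx].any():
                continue
            chosen.append(nd)
            taken[idx] = True
        chosen.sort(key=lambda nd: (-len(members[nd]), heights[nd]))  # type: ignore[arg-type]
        for mid, nd in enumerate(chosen, start=1):
            raw_labels[np.array(members[nd])] = mid
    labels = pd.Series(raw_labels, index=pd.Index(genes, name="gene"))
    return ModuleSet(labels=labels, linkage_matrix=Z, cut_height=None)


def module_eigengenes(dataset: ExpressionDataset, labels: pd.Series) -> pd.DataFrame:
    """First singular vector of each module's standardized expression.

    Each eigengene is scaled to unit variance over samples and oriented so it
    correlates positively with the module's mean standardized expression.
    """
    missing = [g for g in labels.index if g not in dataset.genes]
    if missing:
        raise CoexpressionError(f"labels cover genes absent from dataset: {missing[:5]}")
    mes = {}
    for mid in sorted(set(labels) - {0}):
        genes = labels.index[labels == mid]
        X = dataset.matrix.loc[genes].to_numpy(dtype=float)
        Xs = _standardize_rows(X)
        if Xs.shape[0] == 1:
            me = Xs[0]
        else:
            _, _, vt = np.linalg.svd(Xs, full_matrices=False)
            me = vt[0]
        me = me / me.std(ddof=0)
        mean_profile = Xs.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        mes[f"M{mid}"] = me
    return pd.DataFrame(mes, index=dataset.samples).T


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: TraitEncoding
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait, with p-values.

    p-values are two-sided from the t distribution with n - 2 df and are
    reported unadjusted.
    """
    trait_frame = traits.as_frame()
    n = eigengenes.shape[1]
    if n < 3:
        raise CoexpressionError("need at least 3 samples for trait correlation")
    rows = []
    for trait_name in trait_frame.columns:
        t_vec = trait_frame[trait_name].to_numpy(dtype=float)
        if np.std(t_vec) == 0:
            raise CoexpressionError(f"trait {trait_name!r} has zero variance")
        for module in eigengenes.index:
            me = eigengenes.loc[module].to_numpy(dtype=float)
            r = float(np.corrcoef(me, t_vec)[0, 1])
            r_c = min(max(r, -1.0), 1.0)
            if abs(r_c) == 1.0:
                p = 0.0
            else:
                tstat = r_c * np.sqrt((n - 2) / (1 - r_c**2))
                p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
            rows.append({"module": module, "trait": trait_name, "cor": r, "p": p})
    return pd.DataFrame(rows)


def intramodular_connectivity(adj: np.ndarray, genes: Sequence[str], labels: pd.Series) -> pd.Series:
    """kIM_i: summed adjacency of gene i to the other genes of its module."""
    genes = list(genes)
    A = np.asarray(adj, dtype=float)
    idx = {g: i for i, g in enumerate(genes)}
    kim = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    for mid in sorted(set(labels) - {0}):
        members = [g for g in genes if labels.get(g, 0) == mid]
        rows = [idx[g] for g in members]
        sub = A[np.ix_(rows, rows)].copy()
        np.fill_diagonal(sub, 0.0)
        kim[members] = sub.sum(axis=1)
    return kim


def intramodular_hubs(
    adj: np.ndarray,
    genes: Sequence[str],
    labels: pd.Series,
    top_n: int = 10,
) -> dict[int, pd.DataFrame]:
    """Per-module hub genes ranked by kIM (ties broken by gene ID)."""
    kim = intramodular_connectivity(adj, genes, labels)
    hubs: dict[int, pd.DataFrame] = {}
    for mid in sorted(set(labels) - {0}):
        members = labels.index[labels == mid]
        ranked = (
            pd.DataFrame({"gene": members, "kim": kim[members].to_numpy()})
            .sort_values(["kim", "gene"], ascending=[False, True], kind="mergesort")
            .head(top_n)
            .reset_index(drop=True)
        )
        hubs[mid] = ranked
    return hubs


def build_module_set(
    dataset: ExpressionDataset,
    powers: Sequence[int] = DEFAULT_POWERS,
    r2_threshold: float = 0.8,
    min_module_size: int = 150,
    cut_quantile: float = 0.99,
    n_bins: int = 10,
    power: int | None = None,
) -> tuple[ModuleSet, ScaleFreeFit | None, int]:
    """Full construction: similarity -> power -> TOM -> modules -> summaries.

    When *power* is given the scale-free selection is skipped.  Returns the
    populated :class:`ModuleSet`, the fit table (None when power was forced)
    and the power used.
    """
    S = signed_similarity(dataset)
    fit = None
    if power is None:
        fit = scale_free_fit(S, powers=powers, n_bins=n_bins)
        power, _ = select_power(fit, r2_threshold=r2_threshold)
    A = adjacency(S, power)
    tom = topological_overlap(A)
    modules = cluster_modules(
        tom, S.index, min_module_size=min_module_size, cut_quantile=cut_quantile
    )
    if modules.module_ids:
        modules.eigengenes = module_eigengenes(dataset, modules.labels)
        traits = TraitEncoding.from_dataset(dataset)
        modules.trait_cor = module_trait_correlation(modules.eigengenes, traits)
    modules.kim = intramodular_connectivity(A, S.index, modules.labels)
    return modules, fit, power
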