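"""Co-expression modules, eigengenes and hub genes.

Genes pass an unsupervised variance filter (per-gene sample variances are
modeled with a maximum-likelihood inverse-gamma fit; genes in the upper
tail at p < 0.1 are kept). The unsigned weighted network raises |Pearson
correlation| to a soft-threshold power beta, chosen as the smallest
exponent giving an approximately scale-free degree distribution; genes are
clustered by average linkage on topological-overlap dissimilarity and the
dendrogram is cut at a fixed height with a minimum module size, small or
late-merging genes falling into the unassigned module 0. Eigengenes are
first principal components of module expression; hubs are the top-10
genes by within-module connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError


# ---------------------------------------------------------------------------
# variance filter


def filter_variance(expr: pd.DataFrame, p_threshold: float = 0.1) -> list[str]:
    """Genes whose sample variance lies in the inverse-gamma upper tail.

    ``expr`` is log2 normalized expression, genes x samples. Falls back to
    the top variance decile when the fit degenerates.
    """
    if expr.shape[1] < 3:
        raise InputError("need >= 3 samples for the variance filter")
    variances = expr.var(axis=1, ddof=1)
    positive = variances[variances > 0]
    if positive.nunique() <= 1 or len(positive) < 10:
        warnings.warn("degenerate variance distribution; keeping top decile", stacklevel=2)
        cut = variances.quantile(0.9)
        return list(variances.index[variances > cut])
    try:
        a, loc, scale = stats.invgamma.fit(positive.to_numpy(), floc=0.0)
        pvals = stats.invgamma.sf(variances.to_numpy(), a, loc, scale)
    except Exception:  # pragma: no cover - scipy fit failure
        warnings.warn("inverse-gamma fit failed; keeping top decile", stacklevel=2)
        cut = variances.quantile(0.9)
        return list(variances.index[variances > cut])
    return list(variances.index[pvals < p_threshold])


# ---------------------------------------------------------------------------
# network construction


def adjacency_matrix(expr: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned weighted adjacency |cor|^beta with zeroed diagonal."""
    corr = np.corrcoef(expr.to_numpy())
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log linear fit of the binned connectivity
    distribution (negative when frequency rises with connectivity)."""
    k = adj.sum(axis=1)
    if np.allclose(k, k[0]):
        return 0.0
    hist, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = (hist > 0) & (centers > 0)
    if mask.sum() < 3:
        return 0.0
    x = np.log10(centers[mask])
    y = np.log10(hist[mask] / hist.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(-np.sign(r) * r**2)


def pick_beta(
    expr: pd.DataFrame,
    r2_target: float = 0.8,
    max_beta: int = 20,
    default_beta: int = 6,
    min_mean_connectivity: float = 1.0,
) -> int:
    """Smallest integer exponent reaching the scale-free fit target while
    the network retains usable density (mean connectivity >= 1).

    High exponents trivially satisfy the fit criterion on a near-empty
    network, so candidates below the connectivity floor are skipped. When
    no exponent qualifies (block-structured or small networks routinely
    defeat the scale-free criterion), fall back to the conventional
    unsigned-network default."""
    for beta in range(1, max_beta + 1):
        adj = adjacency_matrix(expr, beta)
        if adj.sum(axis=1).mean() < min_mean_connectivity:
            break
        if scale_free_fit(adj) >= r2_target:
            return beta
    return default_beta


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix."""
    n = adj.shape[0]
    shared = adj @ adj
    k = adj.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (shared + adj) / denom
    tom[np.arange(n), np.arange(n)] = 1.0
    return tom


# ---------------------------------------------------------------------------
# modules


@dataclass
class ModuleSet:
    membership: pd.Series  # gene -> module id (0 = unassigned)
    beta: int
    eigengenes: pd.DataFrame | None = None  # samples x modules
    hubs: dict[int, list[str]] | None = None

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, mod in self.membership.items():
            if mod != 0:
                out.setdefault(int(mod), []).append(gene)
        return out


def build_modules(
    expr: pd.DataFrame,
    min_size: int = 30,
    beta: int | None = None,
    cut_height_frac: float = 0.99,
) -> ModuleSet:
    """Cluster genes into co-expression modules.

    Average-linkage hierarchical clustering on 1 - TOM, cut at a fixed
    fraction of the maximum merge height; clusters below ``min_size`` are
    assigned to module 0. Module ids are 1..m by decreasing size.
    """
    genes = list(expr.index)
    if len(genes) < min_size:
        raise InputError(f"need >= {min_size} genes, have {len(genes)}")
    if beta is None:
        beta = pick_beta(expr)
    adj = adjacency_matrix(expr, beta)
    dissim = 1.0 - topological_overlap(adj)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    cut = cut_height_frac * link[:, 2].max()
    raw_labels = hierarchy.fcluster(link, t=cut, criterion="distance")

    sizes = pd.Series(raw_labels).value_counts()
    big = sizes.index[sizes >= min_size]
    order = sorted(big, key=lambda lbl: -sizes[lbl])
    relabel = {lbl: i + 1 for i, lbl in enumerate(order)}
    membership = pd.Series(
        [relabel.get(lbl, 0) for lbl in raw_labels], index=genes, name="module"
    )
    if membership.nunique() == 1 and membership.iloc[0] != 0:
        warnings.warn("all genes fell into a single module", stacklevel=2)
    return ModuleSet(membership=membership, beta=beta)


def summarize_modules(mods: ModuleSet, expr: pd.DataFrame, n_hubs: int = 10) -> ModuleSet:
    """Attach eigengenes (first PC of the module's scaled expression, sign
    aligned with the module mean profile) and top connectivity hubs."""
    adj = adjacency_matrix(expr, mods.beta)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    eig = {}
    hubs: dict[int, list[str]] = {}
    for mod, genes in sorted(mods.modules().items()):
        sub = expr.loc[genes].to_numpy()
        scaled = (sub - sub.mean(axis=1, keepdims=True)) / np.where(
            sub.std(axis=1, keepdims=True) == 0, 1.0, sub.std(axis=1, keepdims=True)
        )
        # first right singular vector = per-sample eigengene scores
        _, _, vt = np.linalg.svd(scaled, full_matrices=False)
        score = vt[0]
        mean_profile = scaled.mean(axis=0)
        if np.corrcoef(score, mean_profile)[0, 1] < 0:
            score = -score
        eig[f"M{mod}"] = score
        idx = [gene_pos[g] for g in genes]
        sub_adj = adj[np.ix_(idx, idx)]
        connectivity = pd.Series(sub_adj.sum(axis=1), index=genes)
        hubs[mod] = list(connectivity.sort_values(ascending=False).index[:n_hubs])
    mods.eigengenes = pd.DataFrame(eig, index=expr.columns)
    mods.hubs = hubs
    return mods
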