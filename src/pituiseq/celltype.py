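"""Cell-type enrichment, deconvolution and cell-weighted fold-changes.

Module genes are tested per cell type with a one-sided two-sample KS
statistic (within-type expression stochastically greater than expression
in all other cells), then modules are scored for enrichment of
KS-significant genes with an upper-tail hypergeometric test. Bulk samples
are deconvolved against a signature matrix (per-type mean expression over
the reference's top-variance genes) by non-negative least squares with a
final simplex renormalization. Sex differences in estimated proportions
use exact two-sided Wilcoxon rank-sum tests per age and cell type.
Finally, each sex-biased gene's bulk fold-change is redistributed over
cell types in proportion to the gene's signature specificity and the
cell-type proportions, giving a cell-weighted fold-change (cwFC); a gene
is called cell-type-specific where its gene-normalized |cwFC| exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InputError
from .normalize_de import bh_adjust


# ---------------------------------------------------------------------------
# KS enrichment of module genes


def ks_greater(in_type: np.ndarray, others: np.ndarray) -> tuple[float, float]:
    """One-sided two-sample KS: within-type values stochastically greater.

    D = sup_x (ECDF_others(x) - ECDF_in(x)); the p-value uses the one-sided
    asymptotic tail exp(-2 D^2 nm/(n+m)).
    """
    in_type = np.sort(np.asarray(in_type, float))
    others = np.sort(np.asarray(others, float))
    n, m = len(in_type), len(others)
    if n == 0 or m == 0:
        raise InputError("empty sample in KS test")
    grid = np.concatenate([in_type, others])
    cdf_in = np.searchsorted(in_type, grid, side="right") / n
    cdf_out = np.searchsorted(others, grid, side="right") / m
    d = float(np.clip((cdf_out - cdf_in).max(), 0.0, 1.0))
    p = float(min(1.0, np.exp(-2.0 * d * d * n * m / (n + m))))
    return d, p


def ks_celltype_enrichment(
    module_genes, cell_expr: pd.DataFrame, labels: pd.Series, min_cells: int = 20
) -> pd.DataFrame:
    """Per (module gene, cell type) one-sided KS tests with pooled BH FDR.

    ``cell_expr`` is cells x genes; ``labels`` maps cell -> cell type.
    Genes absent from the reference are skipped and logged in the result
    attribute ``skipped``.
    """
    labels = labels.loc[cell_expr.index]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise InputError("need >= 2 cell types")
    counts = labels.value_counts()
    small = counts[counts < min_cells]
    if len(small):
        raise InputError(f"cell types below {min_cells} cells: {dict(small)}")

    masks = {ct: (labels == ct).to_numpy() for ct in types}
    rows, skipped = [], []
    for gene in module_genes:
        if gene not in cell_expr.columns:
            skipped.append(gene)
            continue
        v = cell_expr[gene].to_numpy(float)
        for ct in types:
            d, p = ks_greater(v[masks[ct]], v[~masks[ct]])
            rows.append((gene, ct, d, p))
    out = pd.DataFrame(rows, columns=["gene", "celltype", "D", "p"])
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    out.attrs["skipped"] = skipped
    return out


def module_celltype_enrichment(
    ks: pd.DataFrame, membership: pd.Series, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of KS-significant genes.

    Universe N = all module genes KS-tested; K = universe genes significant
    in the cell type; n = module size within the universe; k = significant
    module genes. p = P(X >= k) under Hypergeom(N, K, n).
    """
    universe = sorted(set(ks.gene))
    n_universe = len(universe)
    sig = ks[ks.FDR <= fdr_max]
    sig_by_type = {ct: set(sub.gene) for ct, sub in sig.groupby("celltype")}
    rows = []
    for mod in sorted(set(membership.loc[membership.index.isin(universe)])):
        if mod == 0:
            continue
        mod_genes = set(membership.index[membership == mod]) & set(universe)
        n = len(mod_genes)
        for ct in sorted(set(ks.celltype)):
            hits = sig_by_type.get(ct, set())
            K = len(hits)
            k = len(mod_genes & hits)
            if k > min(K, n):
                raise InputError("inconsistent hypergeometric counts")
            p = float(stats.hypergeom.sf(k - 1, n_universe, K, n))
            rows.append((mod, ct, n, K, k, p))
    out = pd.DataFrame(rows, columns=["module", "celltype", "n", "K", "k", "p"])
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# signature + deconvolution


@dataclass
class SignatureMatrix:
    S: pd.DataFrame  # genes x celltypes, CPM scale
    marker_type: pd.Series  # gene -> cell type of maximal expression


@dataclass
class ProportionEstimate:
    proportions: pd.DataFrame  # samples x celltypes, rows on the simplex
    residual_norm: pd.Series


def build_signature(
    cell_expr: pd.DataFrame, labels: pd.Series, n_top_variance: int = 3000
) -> SignatureMatrix:
    """Per-type mean expression restricted to the reference's top-variance
    genes, CPM-normalized per cell before averaging."""
    labels = labels.loc[cell_expr.index]
    depth = cell_expr.sum(axis=1).replace(0, 1)
    cpm = cell_expr.div(depth, axis=0) * 1e6
    variances = cpm.var(axis=0, ddof=1)
    top = variances.sort_values(ascending=False).index[:n_top_variance]
    means = cpm[top].groupby(labels).mean().T  # genes x celltypes
    means = means[sorted(means.columns)]
    nonzero = means.sum(axis=1) > 0
    means = means.loc[nonzero]
    return SignatureMatrix(S=means, marker_type=means.idxmax(axis=1))


def deconvolve(
    signature: SignatureMatrix, bulk: pd.DataFrame, min_shared: int = 10
) -> ProportionEstimate:
    """Simplex-constrained proportions per bulk sample.

    Solves min ||S p - b||_2 with p >= 0 on CPM-scaled vectors over the
    genes shared between signature and bulk, then renormalizes p to sum
    to 1."""
    shared = [g for g in signature.S.index if g in bulk.index]
    if len(shared) < min_shared:
        raise InputError(f"only {len(shared)} genes shared between signature and bulk")
    S = signature.S.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn(
            f"rank-deficient signature (cond={np.linalg.cond(S):.3g})", stacklevel=2
        )
    depth = bulk.sum(axis=0).replace(0, 1)
    bulk_cpm = bulk.loc[shared].div(depth, axis=1) * 1e6
    props, residuals = {}, {}
    for sample in bulk.columns:
        b = bulk_cpm[sample].to_numpy(float)
        p, rnorm = optimize.nnls(S, b)
        total = p.sum()
        props[sample] = p / total if total > 0 else np.full(len(p), 1.0 / len(p))
        residuals[sample] = rnorm
    out = pd.DataFrame(props, index=signature.S.columns).T
    return ProportionEstimate(out, pd.Series(residuals, name="residual_norm"))


def test_proportion_sex_difference(
    est: ProportionEstimate, meta: pd.DataFrame, min_per_group: int = 3
) -> pd.DataFrame:
    """Two-sided exact Wilcoxon rank-sum per (age, cell type); raw p-values
    (no multiplicity adjustment). With ties the midrank statistic and
    normal approximation are used and flagged."""
    props = est.proportions
    meta = meta.loc[props.index]
    ages = sorted(meta["age"].unique()) if "age" in meta.columns else ["all"]
    rows = []
    for age in ages:
        sel = meta["age"] == age if "age" in meta.columns else pd.Series(True, index=meta.index)
        f_idx = props.index[(meta.sex == "F") & sel]
        m_idx = props.index[(meta.sex == "M") & sel]
        if len(f_idx) < min_per_group or len(m_idx) < min_per_group:
            raise InputError(f"need >= {min_per_group} samples per sex at {age}")
        for ct in props.columns:
            x, y = props.loc[f_idx, ct], props.loc[m_idx, ct]
            has_ties = pd.concat([x, y]).duplicated().any()
            method = "asymptotic" if has_ties else "exact"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append((age, ct, float(res.pvalue), method))
    return pd.DataFrame(rows, columns=["age", "celltype", "p", "method"])


def mixture_benchmark(
    signature: SignatureMatrix,
    n_samples: int = 50,
    depth: float = 1e6,
    dispersion: float = 0.01,
    seed: int = 0,
) -> float:
    """Mean absolute proportion error on simulated NB-noised mixtures.

    Mixtures are drawn from the signature itself at technical-replicate
    noise levels (a mixing experiment, not biological replication), so the
    result isolates the deconvolution step. Returns the MAE over samples
    and cell types."""
    rng = np.random.default_rng(seed)
    S = signature.S.to_numpy(float)
    rel = S / S.sum(axis=0, keepdims=True)
    k = S.shape[1]
    size = 1.0 / dispersion
    errs = []
    for i in range(n_samples):
        p = rng.dirichlet(np.ones(k))
        mu = depth * rel @ p
        b = rng.negative_binomial(size, size / (size + mu)).astype(float)
        est = deconvolve(signature, pd.DataFrame({"mix": b}, index=signature.S.index))
        errs.append(np.abs(est.proportions.to_numpy()[0] - p).mean())
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# cell-weighted fold-change


def compute_cwfc(
    de: pd.DataFrame,
    signature: SignatureMatrix,
    proportions: ProportionEstimate,
    meta: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Redistribute bulk sex-biased fold-changes over cell types.

    cwfc(g,c) = log2FC(g) * specificity(g,c) * r(c), where specificity is
    the gene's signature row normalized to sum 1 and r(c) averages the two
    sexes' mean estimated proportions. cwfc_norm divides by the gene's
    total |cwfc|; |cwfc_norm| > 0.5 calls the gene in that cell type.
    Genes absent from the signature (or with all-zero rows) are dropped
    and reported via the ``dropped`` attribute.
    """
    props = proportions.proportions
    meta = meta.loc[props.index]
    r = (
        props.groupby(meta.sex.to_numpy()).mean().mean(axis=0)
    )  # mean over sexes of per-sex mean proportions
    rows, dropped = [], []
    for _, rec in de.iterrows():
        gene, lfc = rec["gene"], float(rec["log2FC"])
        if gene not in signature.S.index:
            dropped.append(gene)
            continue
        s = signature.S.loc[gene].to_numpy(float)
        if s.sum() <= 0:
            dropped.append(gene)
            continue
        w = s / s.sum()
        cwfc = lfc * w * r.to_numpy()
        denom = np.abs(cwfc).sum()
        norm = cwfc / denom if denom > 0 else np.zeros_like(cwfc)
        for ct, raw, nv in zip(signature.S.columns, cwfc, norm):
            rows.append((gene, ct, float(raw), float(nv), abs(nv) > threshold))
    out = pd.DataFrame(rows, columns=["gene", "celltype", "cwfc", "cwfc_norm", "called"])
    out.attrs["dropped"] = dropped
    return out
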