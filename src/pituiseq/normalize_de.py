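"""Unwanted-variation removal and negative-binomial differential testing.

Normalization follows the empirical-control-gene strategy: genes showing no
evidence of differential expression across any sex-by-age condition (omnibus
F on log-CPM, FDR >= 0.1) serve as negative controls, and the leading
singular vectors of their centered log-CPM give sample-level unwanted-
variation factors that enter the differential model as covariates. For
batch-confounded small-RNA data, the same factorization runs on log-CPM
centered within biological (sex-by-age) groups, so only non-biological
variation remains before the SVD.

Differential testing fits a per-gene NB log-linear model (cell-means coding
over sex-by-age groups plus the unwanted factors, log library-size offsets)
and uses a likelihood-ratio chi-square for each contrast. Gene dispersions
are method-of-moments estimates shrunk 50/50 toward a trimmed-mean common
dispersion. Sex-biased calls require |FC| > 1.5 and BH FDR < 0.05; the
sex-by-age interaction is called on FDR alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .quantify import CountMatrix

LN2 = np.log(2.0)
FC_MIN = 1.5
FDR_MAX = 0.05


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def log_cpm(cm: CountMatrix, prior: float = 0.5) -> pd.DataFrame:
    return np.log2((cm.counts + prior) * 1e6 / (cm.library_sizes + 1.0))


def _group_labels(meta: pd.DataFrame, samples) -> pd.Series:
    return meta.loc[samples, "sex"].astype(str) + ":" + meta.loc[samples, "age"].astype(str)


# ---------------------------------------------------------------------------
# empirical negative controls


def select_negative_controls(
    cm: CountMatrix, meta: pd.DataFrame, fdr_threshold: float = 0.1, min_controls: int = 50
) -> list[str]:
    """Genes with no omnibus evidence of condition effects (FDR >= 0.1).

    A vectorized one-way F test across all sex-by-age groups on log-CPM;
    zero-variance genes have F = 0 and are always controls.
    """
    groups = _group_labels(meta, cm.samples)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2 or pd.Series(codes).value_counts().min() < 2:
        raise InputError("need >= 2 groups with >= 2 replicates for the omnibus test")
    y = log_cpm(cm).to_numpy()
    n = y.shape[1]
    g = len(uniques)
    grand = y.mean(axis=1, keepdims=True)
    ssb = np.zeros(y.shape[0])
    ssw = np.zeros(y.shape[0])
    for code in range(g):
        sub = y[:, codes == code]
        m = sub.mean(axis=1, keepdims=True)
        ssb += sub.shape[1] * (m[:, 0] - grand[:, 0]) ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (g - 1)) / (ssw / (n - g))
    f = np.where(np.isfinite(f), f, 0.0)
    pvals = stats.f.sf(f, g - 1, n - g)
    fdr = bh_adjust(pvals)
    controls = [gene for gene, q in zip(cm.genes, fdr) if q >= fdr_threshold]
    if len(controls) < min_controls:
        warnings.warn(
            f"only {len(controls)} negative-control genes found; factor estimates may be unstable",
            stacklevel=2,
        )
    return controls


# ---------------------------------------------------------------------------
# unwanted-variation factors


@dataclass
class UnwantedFactors:
    W: pd.DataFrame  # samples x k, orthonormal columns
    method: str  # control_gene_svd | replicate_group_svd
    control_genes: list[str] | None = None

    @property
    def k(self) -> int:
        return self.W.shape[1]


def estimate_unwanted_variation(
    cm: CountMatrix,
    k: int = 1,
    controls: list[str] | None = None,
    meta: pd.DataFrame | None = None,
) -> UnwantedFactors:
    """Leading left singular vectors of centered log-CPM.

    With ``controls``, the SVD runs on control genes centered per gene
    across samples. With ``meta`` (and no controls), log-CPM is centered
    within sex-by-age replicate groups first, removing biology before the
    SVD (the two-batch small-RNA design).
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if k >= len(cm.samples):
        raise InputError(f"k={k} must be smaller than the number of samples")
    y = log_cpm(cm)
    if controls is not None:
        mat = y.loc[[g for g in controls if g in y.index]].to_numpy().T  # samples x genes
        mat = mat - mat.mean(axis=0, keepdims=True)
        method = "control_gene_svd"
    elif meta is not None:
        groups = _group_labels(meta, cm.samples)
        mat = y.to_numpy().T.copy()
        for grp in groups.unique():
            idx = (groups == grp).to_numpy()
            mat[idx] -= mat[idx].mean(axis=0, keepdims=True)
        method = "replicate_group_svd"
    else:
        raise InputError("provide either control genes or sample metadata")
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise InputError(f"k={k} exceeds rank {rank} of the centered matrix")
    W = pd.DataFrame(u[:, :k], index=cm.samples, columns=[f"W{i + 1}" for i in range(k)])
    return UnwantedFactors(W, method, controls)


# ---------------------------------------------------------------------------
# NB GLM with likelihood-ratio contrasts


def estimate_dispersions(cm: CountMatrix, meta: pd.DataFrame, trim: float = 0.2) -> np.ndarray:
    """Per-gene method-of-moments NB dispersions shrunk 50/50 toward the
    trimmed-mean common dispersion (mean/size parameterization,
    var = mu + alpha * mu^2)."""
    groups = _group_labels(meta, cm.samples)
    codes, uniques = pd.factorize(groups)
    scale = cm.library_sizes.to_numpy() / cm.library_sizes.to_numpy().mean()
    z = cm.counts.to_numpy() / scale
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    for code in range(len(uniques)):
        sub = z[:, codes == code]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = sub.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (v - m) / m**2
        d = np.where(np.isfinite(d), d, 0.0)
        num += df * d
        den += df
    raw = np.clip(num / np.maximum(den, 1), 1e-4, 10.0)
    common = float(stats.trim_mean(raw, trim))
    return 0.5 * raw + 0.5 * common


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood, alpha per gene."""
    a = alpha[:, None]
    inv_a = 1.0 / a
    ll = (
        gammaln(y + inv_a)
        - gammaln(inv_a)
        - gammaln(y + 1.0)
        + y * np.log(a * mu / (1.0 + a * mu))
        - inv_a * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def _fit_nb_glm(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray, n_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for NB log-linear models sharing one design matrix.

    Y: genes x samples; X: samples x p; offset: samples (log library
    size); alpha: per-gene dispersion. Returns (beta genes x p, loglik,
    converged mask).
    """
    G, S = Y.shape
    p = X.shape[1]
    # initialize from a working linear model on log scale
    z0 = np.log((Y + 0.5) / np.exp(offset)[None, :])
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # G x p
    ridge = 1e-8 * np.eye(p)
    converged = np.zeros(G, dtype=bool)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset[None, :] + (Y - mu) / mu
        xtwx = np.einsum("sp,gs,sq->gpq", X, w, X) + ridge[None, :, :]
        xtwz = np.einsum("sp,gs,gs->gp", X, w, z)
        try:
            beta_new = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            beta_new = np.stack(
                [np.linalg.lstsq(xtwx[i], xtwz[i], rcond=None)[0] for i in range(G)]
            )
        delta = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        converged = delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    ll = _nb_loglik(Y, np.exp(eta), alpha)
    return beta, ll, converged


def parse_contrast(contrast: str) -> tuple:
    """'sex@PD27' or 'sexXage@PD12:PD22' into a structured tuple."""
    if contrast.startswith("sexXage@"):
        a1, a2 = contrast.split("@", 1)[1].split(":")
        return ("sexXage", a1, a2)
    if contrast.startswith("sex@"):
        return ("sex", contrast.split("@", 1)[1])
    raise InputError(f"unrecognized contrast {contrast!r}")


def test_differential(
    cm: CountMatrix,
    meta: pd.DataFrame,
    contrast: str,
    W: pd.DataFrame | None = None,
    dispersions: np.ndarray | None = None,
    fc_min: float = FC_MIN,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Likelihood-ratio test of one contrast for every gene.

    The full model uses cell-means coding of sex-by-age groups plus any
    unwanted-variation covariates; the reduced model restricts the design
    to the null space of the contrast. log2FC is positive for male-biased
    genes.
    """
    samples = cm.samples
    groups = _group_labels(meta, samples)
    codes, uniques = pd.factorize(groups)
    Xg = np.eye(len(uniques))[codes]  # cell-means design

    kind = parse_contrast(contrast)
    c = np.zeros(len(uniques))
    idx = {g: i for i, g in enumerate(uniques)}
    if kind[0] == "sex":
        age = kind[1]
        for key, sign in ((f"M:{age}", 1.0), (f"F:{age}", -1.0)):
            if key not in idx:
                raise InputError(f"group {key} absent from metadata")
            c[idx[key]] = sign
    else:
        _, a1, a2 = kind
        for key, sign in ((f"M:{a1}", 1.0), (f"F:{a1}", -1.0), (f"M:{a2}", -1.0), (f"F:{a2}", 1.0)):
            if key not in idx:
                raise InputError(f"group {key} absent from metadata")
            c[idx[key]] = sign

    N = linalg.null_space(c[None, :])  # basis of the constrained group space
    Wmat = np.empty((len(samples), 0)) if W is None else W.loc[samples].to_numpy()
    X_full = np.hstack([Xg, Wmat])
    X_red = np.hstack([Xg @ N, Wmat])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise InputError("design matrix is rank deficient")

    Y = cm.counts.to_numpy().astype(float)
    offset = np.log(cm.library_sizes.to_numpy())
    if dispersions is None:
        dispersions = estimate_dispersions(cm, meta)

    beta_f, ll_f, conv_f = _fit_nb_glm(Y, X_full, offset, dispersions)
    _, ll_r, conv_r = _fit_nb_glm(Y, X_red, offset, dispersions)
    stat = np.clip(2.0 * (ll_f - ll_r), 0.0, None)
    # small-sample correction: refer the 1-df statistic to F(1, residual df)
    resid_df = max(1, len(samples) - X_full.shape[1])
    pvals = stats.f.sf(stat, 1, resid_df)
    bad = ~(conv_f & conv_r)
    pvals[bad] = 1.0
    log2fc = (beta_f[:, : len(uniques)] @ c) / LN2
    fdr = bh_adjust(pvals)
    if kind[0] == "sex":
        called = (fdr < fdr_max) & (np.abs(log2fc) > np.log2(fc_min))
    else:
        called = fdr < fdr_max
    return pd.DataFrame(
        {
            "gene": cm.genes,
            "contrast": contrast,
            "log2FC": log2fc,
            "p": pvals,
            "FDR": fdr,
            "called": called,
            "converged": conv_f & conv_r,
        }
    )


def call_sex_biased(
    de_tables: dict[str, pd.DataFrame], fc_min: float = FC_MIN, fdr_max: float = FDR_MAX
) -> dict[str, dict]:
    """Per-age male-/female-biased gene sets plus the interaction set."""
    out: dict[str, dict] = {"male": {}, "female": {}, "interaction": {}}
    for contrast, de in de_tables.items():
        kind = parse_contrast(contrast)
        if kind[0] == "sex":
            sig = de[(de.FDR < fdr_max) & (de.log2FC.abs() > np.log2(fc_min))]
            out["male"][kind[1]] = set(sig.loc[sig.log2FC > 0, "gene"])
            out["female"][kind[1]] = set(sig.loc[sig.log2FC < 0, "gene"])
        else:
            key = f"{kind[1]}:{kind[2]}"
            out["interaction"][key] = set(de.loc[de.FDR < fdr_max, "gene"])
    return out
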