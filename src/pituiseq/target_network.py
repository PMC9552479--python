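"""Sex-biased miRNA to sex-biased target gene anticorrelation network.

Candidate pairs come from prediction (TargetScan-style summary tables,
kept when the cumulative weighted context score is below -0.1) and from
experimental validation (miRTarBase-style tables). Pairs whose miRNA and
gene are both sex-biased at some age are tested for Spearman
anticorrelation on log2 normalized counts over matched samples; edges
require rho < 0 and BH FDR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError
from .normalize_de import bh_adjust

PREDICTED_COLUMNS = {"miRNA", "Gene Symbol", "Cumulative weighted context++ score"}
VALIDATED_COLUMNS = {"miRNA", "Target Gene"}


@dataclass
class TargetPair:
    mirna_id: str
    gene: str
    sources: set[str] = field(default_factory=set)  # {'predicted','validated'}
    context_score: float | None = None


def load_target_pairs(
    predicted: pd.DataFrame | None,
    validated: pd.DataFrame | None,
    score_max: float = -0.1,
) -> list[TargetPair]:
    """Merge predicted (score-filtered, strictly below ``score_max``) and
    validated pairs, unifying duplicates across sources."""
    pairs: dict[tuple[str, str], TargetPair] = {}
    if predicted is not None:
        missing = PREDICTED_COLUMNS - set(predicted.columns)
        if missing:
            raise FormatError(f"predicted table missing columns: {sorted(missing)}")
        for mirna, gene, score in zip(
            predicted["miRNA"],
            predicted["Gene Symbol"],
            predicted["Cumulative weighted context++ score"],
        ):
            score = float(score)
            if score < score_max:
                pair = pairs.setdefault((mirna, gene), TargetPair(mirna, gene))
                pair.sources.add("predicted")
                pair.context_score = score
    if validated is not None:
        missing = VALIDATED_COLUMNS - set(validated.columns)
        if missing:
            raise FormatError(f"validated table missing columns: {sorted(missing)}")
        for mirna, gene in zip(validated["miRNA"], validated["Target Gene"]):
            pair = pairs.setdefault((mirna, gene), TargetPair(mirna, gene))
            pair.sources.add("validated")
    return list(pairs.values())


# ---------------------------------------------------------------------------
# Spearman correlation


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Average-rank Spearman coefficient (Pearson on midranks)."""
    rx, ry = _average_ranks(np.asarray(x, float)), _average_ranks(np.asarray(y, float))
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise InputError("constant vector: rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_test(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """(rho, two-sided p). Exact permutation null for n <= exact_max_n,
    t approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise InputError("x and y must have equal length")
    if n < 3:
        raise InputError("need >= 3 observations")
    rho = spearman_rho(x, y)
    if n <= exact_max_n:
        rx, ry = _average_ranks(x), _average_ranks(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = float(np.mean(rx * ry[list(perm)]))
            hits += abs(r) >= target
            total += 1
        return rho, hits / total
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# network construction


def correlate_pairs(
    pairs: list[TargetPair],
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    sex_biased_mirnas: set[str],
    sex_biased_genes: set[str],
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Test eligible pairs for negative Spearman correlation.

    Expression tables are log2 normalized counts (rows = features,
    columns = samples); samples are matched by intersecting column names.
    Returns one row per tested pair with edge flags, plus a reason for
    skipped pairs.
    """
    matched = [s for s in mirna_expr.columns if s in set(gene_expr.columns)]
    if len(matched) < 5:
        raise InputError(f"need >= 5 matched samples, found {len(matched)}")

    rows = []
    for pair in pairs:
        if pair.mirna_id not in sex_biased_mirnas or pair.gene not in sex_biased_genes:
            continue
        if pair.mirna_id not in mirna_expr.index or pair.gene not in gene_expr.index:
            rows.append((pair.mirna_id, pair.gene, np.nan, np.nan, "missing_expression"))
            continue
        x = mirna_expr.loc[pair.mirna_id, matched].to_numpy(float)
        y = gene_expr.loc[pair.gene, matched].to_numpy(float)
        try:
            rho, p = spearman_test(x, y)
        except InputError:
            rows.append((pair.mirna_id, pair.gene, np.nan, np.nan, "constant_vector"))
            continue
        rows.append((pair.mirna_id, pair.gene, rho, p, ""))
    edges = pd.DataFrame(rows, columns=["mirna_id", "gene", "rho", "p", "skip_reason"])
    tested = edges.skip_reason == ""
    edges["FDR"] = np.nan
    edges.loc[tested, "FDR"] = bh_adjust(edges.loc[tested, "p"].to_numpy())
    edges["negative_significant"] = tested & (edges.rho < 0) & (edges.FDR < fdr_max)
    return edges


def network_tables(edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the significant anticorrelation network."""
    sig = edges[edges.negative_significant].copy()
    mir_deg = sig.mirna_id.value_counts().rename_axis("node").rename("degree").reset_index()
    mir_deg["kind"] = "miRNA"
    gene_deg = sig.gene.value_counts().rename_axis("node").rename("degree").reset_index()
    gene_deg["kind"] = "gene"
    return pd.concat([mir_deg, gene_deg], ignore_index=True), sig
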