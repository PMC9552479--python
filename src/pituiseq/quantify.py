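"""3'-end read counting against an augmented annotation, CPM filtering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AugmentedAnnotation
from .errors import InputError

DEFAULT_EXCLUDE_PREFIXES = ("mt-", "ERCC-")


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with per-sample library sizes.

    Library sizes are fixed at construction (total assigned reads) and are
    deliberately not recomputed after row exclusions, so CPM stays
    comparable across filtering steps.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise InputError(f"samples without library size: {sorted(missing)}")
        self.library_sizes = self.library_sizes[self.counts.columns].astype(float)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CountMatrix":
        return cls(counts, counts.sum(axis=0))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def cpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.library_sizes

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.library_sizes)


def count_reads(
    placements: pd.DataFrame, augmented: AugmentedAnnotation, mapq_min: int = 255
) -> CountMatrix:
    """Count placements whose 3'-end falls in exactly one gene's countable
    intervals (exons with extensions folded in, plus novel polyA features)
    on the same strand. Multi-gene hits are discarded.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gid in augmented.gene_ids():
        g = augmented.base[gid]
        key = (g.chrom, g.strand)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in augmented.countable_intervals(gid):
            tree.addi(s, e + 1, gid)

    ok = placements[placements.mapq >= mapq_min]
    samples = sorted(placements["sample"].unique())
    genes = augmented.gene_ids()
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)

    for row in ok.itertuples(index=False):
        tree = trees.get((row.chrom, row.strand))
        if tree is None:
            continue
        hits = {iv.data for iv in tree.at(row.pos_3prime)}
        if len(hits) == 1:
            mat.loc[hits.pop(), row.sample] += 1
    return CountMatrix.from_counts(mat)


def cpm_and_filter(
    cm: CountMatrix,
    cpm_min: float = 2.0,
    min_samples: int = 10,
    exclude_prefixes: tuple[str, ...] = DEFAULT_EXCLUDE_PREFIXES,
) -> CountMatrix:
    """Drop excluded identifier prefixes, then keep genes with CPM strictly
    above ``cpm_min`` in at least ``min_samples`` samples."""
    if len(cm.samples) < min_samples:
        raise InputError(
            f"need >= {min_samples} samples for the expression filter, have {len(cm.samples)}"
        )
    keep_rows = [g for g in cm.genes if not str(g).startswith(exclude_prefixes)]
    counts = cm.counts.loc[keep_rows]
    cpm = counts * 1e6 / cm.library_sizes
    retained = counts.index[(cpm > cpm_min).sum(axis=1) >= min_samples]
    if len(retained) == 0:
        raise InputError(
            "expression filter removed every gene; review cpm_min/min_samples thresholds"
        )
    return CountMatrix(counts.loc[retained], cm.library_sizes)
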