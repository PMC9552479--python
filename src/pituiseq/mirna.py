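"""Small-RNA preprocessing and mirtron annotation.

miRNA-sized reads are an exact length window (18-22 nt after adapter
trimming). A precursor locus is a mirtron when it sits fully inside an
intron of a same-strand gene without touching any exon of that gene —
i.e. it is excised by splicing rather than canonical cropping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .annotation import GeneAnnotation

MIN_LEN = 18
MAX_LEN = 22  # strictly less than 23 nt


@dataclass
class PrecursorLocus:
    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    classification: str  # mirtron | exonic_overlap | intergenic
    host_gene: str | None = None
    intron_ordinal: str | None = None  # '1', '2', ... or 'last'


def srna_length_ok(length: int, min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> bool:
    return min_len <= length <= max_len


def preprocess_srna(reads, min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> list:
    """Retain adapter-trimmed reads within the miRNA length window."""
    return [r for r in reads if srna_length_ok(len(r.sequence), min_len, max_len)]


def annotate_mirtron(
    mirna_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    annotation: GeneAnnotation,
) -> PrecursorLocus:
    """Classify one precursor locus against gene models (1-based inclusive)."""
    chroms = {g.chrom for g in annotation}
    if chrom not in chroms:
        warnings.warn(f"{mirna_id}: chromosome {chrom} not annotated; classified intergenic", stacklevel=2)
        return PrecursorLocus(mirna_id, chrom, start, end, strand, "intergenic")

    overlapping = [
        g
        for g in annotation
        if g.chrom == chrom and start <= g.end and g.start <= end
    ]
    for g in overlapping:
        if g.strand != strand:
            continue
        introns = g.introns
        for i, (s, e) in enumerate(introns):
            inside = s <= start and end <= e
            touches_exon = any(start <= ee and es <= end for es, ee in g.exons)
            if inside and not touches_exon:
                # ordinal in transcription direction
                n = len(introns)
                ordinal_idx = i + 1 if g.strand == "+" else n - i
                ordinal = "last" if ordinal_idx == n else str(ordinal_idx)
                return PrecursorLocus(
                    mirna_id, chrom, start, end, strand, "mirtron", g.gene_id, ordinal
                )
    if any(
        any(start <= ee and es <= end for es, ee in g.exons) for g in overlapping
    ):
        return PrecursorLocus(mirna_id, chrom, start, end, strand, "exonic_overlap")
    # overlapping a gene without touching exons (antisense or boundary-
    # crossing intronic) is not splicing-derived; grouped with intergenic
    return PrecursorLocus(mirna_id, chrom, start, end, strand, "intergenic")
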