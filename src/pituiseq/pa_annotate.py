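"""PolyA-site discovery and annotation augmentation.

The 3'-most nucleotide of every read builds a per-sample, per-strand
signal track; maximal runs of positions whose cross-sample mean coverage
clears an RPM cutoff become expressed regions (ERs). Intronic and
intergenic ERs are screened for internal oligo(dT)-priming artifacts by
examining the genomic sequence immediately downstream (A-rich sequence on
the transcribed strand betrays a spurious priming site) and for repeat
overlap. Surviving ERs are assigned to genes — known 3'UTRs first, then
intronic polyA sites, then 3'UTR extensions within 5 kb downstream — and
the gene models are augmented accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AugmentedAnnotation, GeneAnnotation
from .errors import InputError
from .io import revcomp

ELIGIBLE_CATEGORIES = {"intron", "intergenic"}


# ---------------------------------------------------------------------------
# signal track


class SignalTrack:
    """Per (chrom, strand, sample) pileup of read 3'-end positions."""

    def __init__(self):
        self.counts: dict[tuple[str, str], dict[str, dict[int, int]]] = {}
        self.library_sizes: dict[str, int] = {}

    @property
    def samples(self) -> list[str]:
        return sorted(self.library_sizes)

    def add(self, sample: str, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        per_sample = self.counts.setdefault((chrom, strand), {})
        pile = per_sample.setdefault(sample, {})
        pile[pos] = pile.get(pos, 0) + n
        self.library_sizes[sample] = self.library_sizes.get(sample, 0) + n

    def rpm(self, sample: str, chrom: str, strand: str, pos: int) -> float:
        count = self.counts.get((chrom, strand), {}).get(sample, {}).get(pos, 0)
        return count * 1e6 / self.library_sizes[sample]

    def mean_rpm_profile(self, chrom: str, strand: str) -> dict[int, float]:
        """Cross-sample mean of per-position RPM for one (chrom, strand)."""
        samples = self.samples
        if not samples:
            return {}
        per_sample = self.counts.get((chrom, strand), {})
        profile: dict[int, float] = {}
        for sample in samples:
            lib = self.library_sizes[sample]
            for pos, count in per_sample.get(sample, {}).items():
                profile[pos] = profile.get(pos, 0.0) + count * 1e6 / lib
        n = len(samples)
        return {pos: v / n for pos, v in profile.items()}


def build_end_signal(
    placements: pd.DataFrame, mapq_min: int = 255, genome: dict[str, str] | None = None
) -> SignalTrack:
    """Pile up read 3'-end placements into a signal track.

    Placements with mapq below ``mapq_min`` are excluded; library sizes
    reflect only the included placements.
    """
    if genome is not None:
        unknown = sorted(set(placements.chrom) - set(genome))
        if unknown:
            raise InputError(f"placements reference unknown chromosomes: {unknown}")
    track = SignalTrack()
    ok = placements[placements.mapq >= mapq_min]
    grouped = ok.groupby(["sample", "chrom", "strand", "pos_3prime"], sort=False).size()
    for (sample, chrom, strand, pos), n in grouped.items():
        track.add(sample, chrom, strand, int(pos), int(n))
    # samples whose every placement failed the mapq filter still define a library
    for sample in placements["sample"].unique():
        track.library_sizes.setdefault(sample, 0)
    return track


# ---------------------------------------------------------------------------
# expressed regions


@dataclass
class ExpressedRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    mean_rpm: float
    categories: set[str] = field(default_factory=set)
    filter_status: str = "kept"
    gene: str | None = None
    assign_mode: str = "unassigned"
    assign_reason: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("ER start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_expressed_regions(track: SignalTrack, cutoff_rpm: float = 1.0) -> list[ExpressedRegion]:
    """Maximal runs of consecutive positions with mean RPM >= cutoff."""
    ers: list[ExpressedRegion] = []
    for (chrom, strand) in sorted(track.counts):
        profile = track.mean_rpm_profile(chrom, strand)
        positions = sorted(p for p, v in profile.items() if v >= cutoff_rpm)
        if not positions:
            continue
        run_start = prev = positions[0]
        for pos in positions[1:]:
            if pos == prev + 1:
                prev = pos
                continue
            ers.append(_make_er(chrom, strand, run_start, prev, profile))
            run_start = prev = pos
        ers.append(_make_er(chrom, strand, run_start, prev, profile))
    return ers


def _make_er(chrom, strand, start, end, profile) -> ExpressedRegion:
    mean_rpm = float(np.mean([profile[p] for p in range(start, end + 1)]))
    return ExpressedRegion(chrom, start, end, strand, mean_rpm)


# ---------------------------------------------------------------------------
# classification


def _gene_trees(annotation: GeneAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_regions(ers: list[ExpressedRegion], annotation: GeneAnnotation) -> list[ExpressedRegion]:
    """Attach every overlapping annotation category (strand-agnostic);
    intergenic iff the ER overlaps no gene body."""
    trees = _gene_trees(annotation)
    for er in ers:
        cats: set[str] = set()
        tree = trees.get(er.chrom)
        hits = tree.overlap(er.start, er.end + 1) if tree is not None else []
        for hit in hits:
            g = hit.data
            if g.utr3 and _overlaps(er.start, er.end, *g.utr3):
                cats.add("3UTR")
            if g.utr5 and _overlaps(er.start, er.end, *g.utr5):
                cats.add("5UTR")
            if any(_overlaps(er.start, er.end, s, e) for s, e in g.exons):
                cats.add("exon")
            if any(_overlaps(er.start, er.end, s, e) for s, e in g.introns):
                cats.add("intron")
        er.categories = cats or {"intergenic"}
    return ers


# ---------------------------------------------------------------------------
# internal-priming and repeat filters


def downstream_window(er: ExpressedRegion, genome: dict[str, str], width: int = 150) -> str:
    """Transcribed-strand sequence immediately 3' of the ER's far end,
    truncated at the chromosome boundary."""
    seq = genome[er.chrom]
    if er.strand == "+":
        return seq[er.end : er.end + width]
    lo = max(0, er.start - 1 - width)
    return revcomp(seq[lo : er.start - 1])


def filter_internal_priming(
    er: ExpressedRegion,
    genome: dict[str, str],
    repeats: list[tuple[str, int, int]] | None = None,
) -> str:
    """Screen one intronic/intergenic ER; returns its filter status.

    Drop rules, evaluated on the transcribed-strand downstream sequence:
    (a) any 18-mer within 150 bp with >= 12 A (18-mer polyA, <= 6
    mismatches); (b) any 7-mer within 20 bp with >= 6 A (7-mer polyA, <= 1
    mismatch); (c) > 50% A within the first 20 bp; (d) > 20 bp overlap
    with an annotated repeat. Windows extending past the chromosome end
    are truncated and evaluated on the available bases.
    """
    window = downstream_window(er, genome, 150)
    is_a = np.frombuffer(window.encode(), dtype="S1") == b"A"
    n = len(is_a)
    for i in range(min(n, 150) - 17):
        if is_a[i : i + 18].sum() >= 12:
            return "drop_18mer"
    for i in range(min(n, 20) - 6):
        if is_a[i : i + 7].sum() >= 6:
            return "drop_7mer"
    head = is_a[: min(n, 20)]
    if head.size and head.mean() > 0.5:
        return "drop_Afrac"
    for chrom, rs, re_ in repeats or []:
        if chrom != er.chrom:
            continue
        overlap = min(er.end, re_) - max(er.start, rs) + 1
        if overlap > 20:
            return "drop_repeat"
    return "kept"


def apply_filters(
    ers: list[ExpressedRegion],
    genome: dict[str, str],
    repeats: list[tuple[str, int, int]] | None = None,
) -> list[ExpressedRegion]:
    """Apply artifact filters to ERs eligible for novel-site discovery
    (those mapping only to introns/intergenic space); other ERs keep their
    annotation-supported status untouched."""
    for er in ers:
        if er.categories and er.categories <= ELIGIBLE_CATEGORIES:
            er.filter_status = filter_internal_priming(er, genome, repeats)
        else:
            er.filter_status = "kept"
    return ers


# ---------------------------------------------------------------------------
# assignment and augmentation


def assign_and_augment(
    ers: list[ExpressedRegion],
    refseq_3utrs: list[tuple],
    annotation: GeneAnnotation,
    max_downstream: int = 5000,
    intronic_pad: int = 5,
) -> tuple[AugmentedAnnotation, dict]:
    """Assign kept ERs to genes and augment the annotation.

    Precedence per ER: (1) overlap with a known (RefSeq-style) 3'UTR of a
    same-strand gene — read assignment only; (2) intronic within exactly
    one same-strand gene — novel internal polyA feature, padded
    ``intronic_pad`` bp each side; (3) within ``max_downstream`` bp 3' of a
    same-strand gene end and not inside another gene — 3'UTR extension;
    (4) unassigned. ``refseq_3utrs`` rows are (chrom, start, end, gene_id)
    in 1-based inclusive coordinates.
    """
    utr_trees: dict[str, IntervalTree] = {}
    for chrom, s, e, gid in refseq_3utrs:
        utr_trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, gid)
    gene_trees = _gene_trees(annotation)

    aug = AugmentedAnnotation(base=annotation)
    for er in ers:
        if er.filter_status != "kept":
            continue
        if not (er.categories <= ELIGIBLE_CATEGORIES):
            # annotation-supported ER: counted via the existing gene model
            er.assign_mode = "annotated"
            continue

        # (1) known 3'UTR
        tree = utr_trees.get(er.chrom)
        hit_gid = None
        for hit in tree.overlap(er.start, er.end + 1) if tree is not None else []:
            gid = hit.data
            if gid in annotation.genes and annotation[gid].strand == er.strand:
                hit_gid = gid
                break
        if hit_gid is not None:
            er.gene, er.assign_mode = hit_gid, "refseq_3utr"
            continue

        # (2) intronic host
        hosts = []
        gtree = gene_trees.get(er.chrom)
        for hit in gtree.overlap(er.start, er.end + 1) if gtree is not None else []:
            g = hit.data
            if g.strand == er.strand and any(
                _overlaps(er.start, er.end, s, e) for s, e in g.introns
            ):
                hosts.append(g)
        if len(hosts) > 1:
            er.assign_mode, er.assign_reason = "unassigned", "ambiguous_host"
            continue
        if len(hosts) == 1:
            g = hosts[0]
            er.gene, er.assign_mode = g.gene_id, "intronic"
            aug.novel_pa.setdefault(g.gene_id, []).append(
                (er.start - intronic_pad, er.end + intronic_pad)
            )
            continue

        # (3) downstream extension
        inside_other = any(
            _overlaps(er.start, er.end, hit.data.start, hit.data.end)
            for hit in (gtree.overlap(er.start, er.end + 1) if gtree is not None else [])
        )
        candidate = None
        if not inside_other:
            best_d = None
            for g in annotation:
                if g.chrom != er.chrom or g.strand != er.strand:
                    continue
                if er.strand == "+" and er.start > g.end:
                    d = er.end - g.end
                elif er.strand == "-" and er.end < g.start:
                    d = g.start - er.start
                else:
                    continue
                if d <= max_downstream and (best_d is None or d < best_d):
                    best_d, candidate = d, g
        if candidate is not None:
            er.gene, er.assign_mode = candidate.gene_id, "downstream_5kb"
            if er.strand == "+":
                new = (candidate.end + 1, er.end)
                prev = aug.extensions.get(candidate.gene_id)
                if prev is None or new[1] > prev[1]:
                    aug.extensions[candidate.gene_id] = new
            else:
                new = (er.start, candidate.start - 1)
                prev = aug.extensions.get(candidate.gene_id)
                if prev is None or new[0] < prev[0]:
                    aug.extensions[candidate.gene_id] = new
            continue

        er.assign_mode = "unassigned"

    internal = set(aug.novel_pa)
    extended = set(aug.extensions)
    report = {
        "genes_with_internal_pa": len(internal),
        "genes_with_extension": len(extended),
        "genes_with_both": len(internal & extended),
        "novel_ers": sum(1 for er in ers if er.assign_mode in ("intronic", "downstream_5kb")),
    }
    return aug, report


def er_table(ers: list[ExpressedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": er.chrom,
                "start": er.start,
                "end": er.end,
                "strand": er.strand,
                "mean_rpm": er.mean_rpm,
                "categories": ",".join(sorted(er.categories)),
                "filter_status": er.filter_status,
                "gene": er.gene or "",
                "assign_mode": er.assign_mode,
                "assign_reason": er.assign_reason,
            }
            for er in ers
        ]
    )


def annotate_pa(
    placements: pd.DataFrame,
    genome: dict[str, str],
    annotation: GeneAnnotation,
    refseq_3utrs: list[tuple],
    repeats: list[tuple[str, int, int]] | None = None,
    cutoff_rpm: float = 1.0,
    mapq_min: int = 255,
    max_downstream: int = 5000,
    intronic_pad: int = 5,
) -> tuple[AugmentedAnnotation, list[ExpressedRegion], dict]:
    """Full pipeline: signal track -> ERs -> filters -> augmented annotation."""
    track = build_end_signal(placements, mapq_min=mapq_min, genome=genome)
    ers = detect_expressed_regions(track, cutoff_rpm=cutoff_rpm)
    classify_regions(ers, annotation)
    apply_filters(ers, genome, repeats)
    aug, report = assign_and_augment(
        ers, refseq_3utrs, annotation, max_downstream=max_downstream, intronic_pad=intronic_pad
    )
    return aug, ers, report
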