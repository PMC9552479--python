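"""Gene models and annotation containers.

All internal coordinates are 1-based inclusive (GTF convention). BED input
and output is converted at the I/O boundary (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["Gene", "GeneAnnotation", "AugmentedAnnotation"]


@dataclass(frozen=True)
class Gene:
    """A stranded gene model with exon structure.

    Exons are (start, end) 1-based inclusive tuples sorted by coordinate.
    ``utr3`` is the terminal 3'UTR interval (a sub-interval of the terminal
    exon in the direction of transcription), or ``None``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr3: tuple[int, int] | None = None
    utr5: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in coordinate order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the transcription 3' end."""
        return self.end if self.strand == "+" else self.start


class GeneAnnotation:
    """An ordered collection of :class:`Gene` keyed by gene_id."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def to_gtf(self, path) -> None:
        write_gtf(self, path)


@dataclass
class AugmentedAnnotation:
    """Base annotation plus discovered novel polyA features.

    ``novel_pa`` maps gene_id to intervals flagged as intronic polyA sites
    (already padded); ``extensions`` maps gene_id to the interval by which
    the terminal 3'UTR (and the gene end) was extended downstream.
    """

    base: GeneAnnotation
    novel_pa: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    extensions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def effective_gene(self, gene_id: str) -> Gene:
        """Gene model with its end pushed out by any accepted extension."""
        g = self.base[gene_id]
        ext = self.extensions.get(gene_id)
        if ext is None:
            return g
        s, e = ext
        if g.strand == "+":
            new_end = max(g.end, e)
            exons = g.exons[:-1] + ((g.exons[-1][0], max(g.exons[-1][1], e)),)
            utr3 = None if g.utr3 is None else (g.utr3[0], max(g.utr3[1], e))
            return replace(g, end=new_end, exons=exons, utr3=utr3)
        new_start = min(g.start, s)
        exons = ((min(g.exons[0][0], s), g.exons[0][1]),) + g.exons[1:]
        utr3 = None if g.utr3 is None else (min(g.utr3[0], s), g.utr3[1])
        return replace(g, start=new_start, exons=exons, utr3=utr3)

    def countable_intervals(self, gene_id: str) -> list[tuple[int, int]]:
        """Intervals in which a read 3'-end is attributed to this gene:
        exons (with any 3'UTR extension folded in) plus novel polyA features.
        """
        g = self.effective_gene(gene_id)
        ivs = list(g.exons)
        ivs.extend(self.novel_pa.get(gene_id, []))
        return ivs

    def gene_ids(self) -> list[str]:
        return list(self.base.genes)

    def to_gtf(self, path) -> None:
        write_gtf(self, path)


def _gtf_line(chrom, source, feature, start, end, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return f"{chrom}\t{source}\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}\n"


def write_gtf(ann, path) -> None:
    """Serialize a :class:`GeneAnnotation` or :class:`AugmentedAnnotation`.

    Novel intronic polyA features are written as ``polyA_site`` records and
    tagged with their provenance; extended genes carry an ``extended``
    provenance tag on the gene record.
    """
    if isinstance(ann, AugmentedAnnotation):
        genes = [ann.effective_gene(gid) for gid in ann.base.genes]
        novel_pa = ann.novel_pa
        extended = set(ann.extensions)
    else:
        genes = list(ann)
        novel_pa = {}
        extended = set()
    with open(path, "w") as fh:
        for g in genes:
            attrs = {"gene_id": g.gene_id}
            if g.gene_id in extended:
                attrs["provenance"] = "extended_3utr"
            fh.write(_gtf_line(g.chrom, "pituiseq", "gene", g.start, g.end, g.strand, attrs))
            for s, e in g.exons:
                fh.write(_gtf_line(g.chrom, "pituiseq", "exon", s, e, g.strand, {"gene_id": g.gene_id}))
            if g.utr3 is not None:
                fh.write(_gtf_line(g.chrom, "pituiseq", "three_prime_UTR", g.utr3[0], g.utr3[1], g.strand, {"gene_id": g.gene_id}))
            if g.utr5 is not None:
                fh.write(_gtf_line(g.chrom, "pituiseq", "five_prime_UTR", g.utr5[0], g.utr5[1], g.strand, {"gene_id": g.gene_id}))
            for s, e in novel_pa.get(g.gene_id, []):
                fh.write(
                    _gtf_line(
                        g.chrom, "pituiseq", "polyA_site", s, e, g.strand,
                        {"gene_id": g.gene_id, "provenance": "novel_internal_pa"},
                    )
                )


def read_gtf(path) -> GeneAnnotation:
    """Read a GTF written by :func:`write_gtf` back into gene models.

    Only the feature types this package emits are interpreted.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attr = line.rstrip("\n").split("\t")
            attrs = {}
            for item in attr.strip().split(";"):
                item = item.strip()
                if item:
                    k, v = item.split(" ", 1)
                    attrs[k] = v.strip('"')
            gid = attrs["gene_id"]
            rec = genes.setdefault(gid, {"chrom": chrom, "strand": strand, "exons": [], "utr3": None, "utr5": None, "pa": []})
            start, end = int(start), int(end)
            if feature == "gene":
                rec["start"], rec["end"] = start, end
            elif feature == "exon":
                rec["exons"].append((start, end))
            elif feature == "three_prime_UTR":
                rec["utr3"] = (start, end)
            elif feature == "five_prime_UTR":
                rec["utr5"] = (start, end)
            elif feature == "polyA_site":
                rec["pa"].append((start, end))
    out = []
    for gid, rec in genes.items():
        out.append(
            Gene(
                gene_id=gid,
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                utr3=rec["utr3"],
                utr5=rec["utr5"],
            )
        )
    return GeneAnnotation(out)
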