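"""Synthetic data with known ground truth.

Generates a toy genome with hidden 3'UTR extensions, intronic polyA sites
and internal-priming decoys; 3'-anchored reads with polyA tails bleeding
into adapter; negative-binomial count tables with injected sex/age effects;
and a multi-cell-type reference with sex-dependent mixture proportions.
Every injected signal is recorded in a truth table so downstream stages can
be scored against a recoverable answer.

Truth polyA sites are planted with clean (non-A-rich) downstream sequence:
a genuine cleavage site is, by definition of the internal-priming filter,
one whose downstream genomic context is not oligo(dT)-primable. Decoy loci
get the opposite treatment (an A-rich run immediately downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .annotation import Gene, GeneAnnotation
from .errors import ConfigError, InputError

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
SEXES = ("F", "M")
AGES = ("PD12", "PD22", "PD27", "PD32", "PD37")

# mouse-like base composition
_BASES = np.array(list("ACGT"))
_BASE_P = np.array([0.29, 0.21, 0.21, 0.29])


# ---------------------------------------------------------------------------
# genome truth


@dataclass
class GenomeConfig:
    n_genes: int = 30
    frac_extensions: float = 0.3
    frac_intronic_pa: float = 0.3
    n_decoys: int = 10
    n_repeats: int = 4
    exon1_len: int = 400
    intron_len: int = 1200
    exon2_len: int = 800
    utr3_len: int = 400
    intergenic_gap: int = 9000
    max_extension: int = 1500
    min_extension: int = 300
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_genes", "exon1_len", "intron_len", "exon2_len", "utr3_len", "intergenic_gap"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be positive, got {getattr(self, f)}")
        for f in ("frac_extensions", "frac_intronic_pa"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be in [0, 1], got {v}")
        for f in ("n_decoys", "n_repeats"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be non-negative")
        if not self.min_extension <= self.max_extension <= 5000:
            raise ConfigError("min_extension/max_extension must satisfy min <= max <= 5000")


@dataclass
class TruthBundle:
    genome: dict[str, str]
    annotation: GeneAnnotation
    true_extensions: dict[str, tuple[int, int]]
    true_internal_pa: dict[str, list[int]]
    decoy_arich: list[tuple[str, int, int]]
    decoy_sites: list[tuple[str, int, str]]
    repeats: list[tuple[str, int, int]]
    seed: int
    de_truth: pd.DataFrame | None = None
    mirna_truth: pd.DataFrame | None = None
    celltype_truth: dict | None = None

    def pa_sites(self) -> pd.DataFrame:
        """All true polyA sites: canonical gene ends, extensions, intronic."""
        rows = []
        for g in self.annotation:
            rows.append((g.gene_id, g.chrom, g.three_prime_end, g.strand, "true_pa"))
        for gid, (s, e) in self.true_extensions.items():
            g = self.annotation[gid]
            pos = e if g.strand == "+" else s
            rows.append((gid, g.chrom, pos, g.strand, "extension_pa"))
        for gid, positions in self.true_internal_pa.items():
            g = self.annotation[gid]
            for pos in positions:
                rows.append((gid, g.chrom, pos, g.strand, "intronic_pa"))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand", "label"])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_fasta(self.genome, outdir / "genome.fa")
        self.annotation.to_gtf(outdir / "annotation.gtf")
        pio.write_bed(self.repeats, outdir / "repeats.bed")
        pio.write_bed(self.decoy_arich, outdir / "decoys.bed")
        utr3 = [(g.chrom, g.utr3[0], g.utr3[1], g.gene_id) for g in self.annotation if g.utr3]
        pio.write_bed(utr3, outdir / "refseq_3utr.bed")
        self.pa_sites().to_csv(outdir / "truth_pa_sites.tsv", sep="\t", index=False)
        with open(outdir / "truth_structure.json", "w") as fh:
            json.dump(
                {
                    "true_extensions": self.true_extensions,
                    "true_internal_pa": self.true_internal_pa,
                    "decoy_sites": self.decoy_sites,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_BASE_P)


def _passes_priming_filter(window: str) -> bool:
    """True iff a downstream window would survive the internal-priming rules."""
    w = np.frombuffer(window.encode(), dtype="S1") == b"A"
    n = len(w)
    for i in range(min(n, 150) - 17):
        if w[i : i + 18].sum() >= 12:
            return False
    for i in range(min(n, 20) - 6):
        if w[i : i + 7].sum() >= 6:
            return False
    head = w[: min(n, 20)]
    if head.size and head.mean() > 0.5:
        return False
    return True


def _plant_clean_downstream(rng, chrom_arr: np.ndarray, pos: int, strand: str) -> None:
    """Rewrite the 150 bp downstream of a true site (transcribed strand)
    until it passes the internal-priming filter, and pin the site base to C
    so the cleavage boundary is unambiguous for trimming."""
    n = len(chrom_arr)
    if strand == "+":
        chrom_arr[pos - 1] = "C"
        lo, hi = pos, min(n, pos + 150)  # 0-based downstream slice
        for _ in range(100):
            seg = _random_seq(rng, hi - lo)
            if _passes_priming_filter("".join(seg)):
                chrom_arr[lo:hi] = seg
                return
    else:
        chrom_arr[pos - 1] = "G"  # C on transcribed (minus) strand
        lo, hi = max(0, pos - 151), pos - 1
        for _ in range(100):
            seg = _random_seq(rng, hi - lo)
            if _passes_priming_filter(pio.revcomp("".join(seg))):
                chrom_arr[lo:hi] = seg
                return
    raise RuntimeError("failed to plant clean downstream sequence")  # pragma: no cover


def make_truth_genome(config: GenomeConfig | None = None, **kwargs) -> TruthBundle:
    """Build a toy genome with genes carrying hidden extensions and intronic
    polyA sites, decoy A-rich loci, and repeat intervals."""
    if config is None:
        config = GenomeConfig(**kwargs)
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_span = config.exon1_len + config.intron_len + config.exon2_len
    pitch = gene_span + config.intergenic_gap
    chrom = "chr1"
    chrom_len = config.n_genes * pitch + config.intergenic_gap
    arr = _random_seq(rng, chrom_len)

    genes = []
    for i in range(config.n_genes):
        start = config.intergenic_gap + i * pitch + 1
        e1 = (start, start + config.exon1_len - 1)
        e2 = (e1[1] + config.intron_len + 1, start + gene_span - 1)
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            utr3 = (e2[1] - config.utr3_len + 1, e2[1])
        else:
            utr3 = (e1[0], e1[0] + config.utr3_len - 1)
            e1, e2 = (e1[0], e1[1]), (e2[0], e2[1])
        genes.append(
            Gene(
                gene_id=f"gene{i:03d}",
                chrom=chrom,
                start=start,
                end=start + gene_span - 1,
                strand=strand,
                exons=(e1, e2),
                utr3=utr3,
            )
        )
    annotation = GeneAnnotation(genes)

    n_ext = int(round(config.frac_extensions * config.n_genes))
    n_int = int(round(config.frac_intronic_pa * config.n_genes))
    ids = np.array([g.gene_id for g in genes])
    ext_ids = list(rng.choice(ids, size=n_ext, replace=False))
    int_ids = list(rng.choice(ids, size=n_int, replace=False))

    true_extensions: dict[str, tuple[int, int]] = {}
    for gid in ext_ids:
        g = annotation[gid]
        off = int(rng.integers(config.min_extension, config.max_extension + 1))
        if g.strand == "+":
            pos = g.end + off
            true_extensions[gid] = (g.end + 1, pos)
        else:
            pos = g.start - off
            true_extensions[gid] = (pos, g.start - 1)

    true_internal_pa: dict[str, list[int]] = {}
    for gid in int_ids:
        g = annotation[gid]
        intron = g.introns[0]
        pos = int(rng.integers(intron[0] + 200, intron[1] - 200))
        true_internal_pa[gid] = [pos]

    # sanitize downstream context of every true site
    for _, row in TruthBundle(
        {chrom: ""}, annotation, true_extensions, true_internal_pa, [], [], [], config.seed
    ).pa_sites().iterrows():
        _plant_clean_downstream(rng, arr, int(row.pos), row.strand)

    # decoy A-rich loci in intergenic space, away from genes and extensions
    decoy_sites: list[tuple[str, int, str]] = []
    decoy_arich: list[tuple[str, int, int]] = []
    for i in range(config.n_decoys):
        slot = int(rng.integers(0, config.n_genes))
        base = slot * pitch + 1  # intergenic block before gene `slot`
        pos = base + int(rng.integers(2500, config.intergenic_gap - 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        # A-rich 20-mer downstream on the transcribed strand: exactly 14/20 A
        # so the >50%-A priming rule fires by construction
        run = np.array(list("A" * 14 + "G" * 6))
        rng.shuffle(run)
        if strand == "+":
            arr[pos - 1] = "C"  # unambiguous 3'-end boundary, as at true sites
            arr[pos : pos + 20] = run
            decoy_arich.append((chrom, pos + 1, pos + 20))
        else:
            arr[pos - 1] = "G"
            arr[pos - 21 : pos - 1] = np.array(list(pio.revcomp("".join(run))))
            decoy_arich.append((chrom, pos - 20, pos - 1))
        decoy_sites.append((chrom, pos, strand))

    repeats = []
    for i in range(config.n_repeats):
        slot = int(rng.integers(0, config.n_genes))
        base = slot * pitch + 1
        s = base + int(rng.integers(200, 1200))
        repeats.append((chrom, s, s + int(rng.integers(100, 400))))

    return TruthBundle(
        genome={chrom: "".join(arr)},
        annotation=annotation,
        true_extensions=true_extensions,
        true_internal_pa=true_internal_pa,
        decoy_arich=decoy_arich,
        decoy_sites=decoy_sites,
        repeats=repeats,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadDesign:
    n_samples: int = 10
    reads_per_site: int = 200
    tail_len: int = 10
    adapter: str = DEFAULT_ADAPTER
    internal_priming_rate: float = 0.1
    blocklist_rate: float = 0.05
    read_len: int = 68
    prefix_len: int = 12
    min_insert: int = 38
    max_insert: int = 48
    n_blocklist_seqs: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not self.adapter:
            raise ConfigError("adapter must be non-empty")
        for f in ("internal_priming_rate", "blocklist_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be in [0, 1], got {v}")
        if self.reads_per_site <= 0 or self.n_samples <= 0:
            raise ConfigError("n_samples and reads_per_site must be positive")


@dataclass
class QuantseqReads:
    fastq: dict[str, list[pio.FastqRecord]]
    placements: pd.DataFrame
    read_truth: pd.DataFrame
    blocklist_seqs: dict[str, str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, recs in self.fastq.items():
            pio.write_fastq(recs, outdir / f"{sample}.fastq")
        pio.write_placements(self.placements, outdir / "placements.tsv")
        self.read_truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        pio.write_fasta(self.blocklist_seqs, outdir / "blocklist.fa")


def _transcribed_insert(genome: dict[str, str], chrom: str, pos: int, strand: str, length: int) -> str:
    seq = genome[chrom]
    if strand == "+":
        return seq[pos - length : pos]
    return pio.revcomp(seq[pos - 1 : pos - 1 + length])


def simulate_quantseq_reads(truth: TruthBundle, design: ReadDesign | None = None, **kwargs) -> QuantseqReads:
    """Simulate 3'-anchored reads at every true polyA site plus decoy loci.

    Each raw read is ``12 random nt + genomic insert + polyA tail +
    adapter``, truncated to the read length; a fraction of reads are
    internal-priming artifacts placed at decoy loci, and a fraction are
    blocklist (rRNA/BC1-like) sequence that never maps.
    """
    if design is None:
        design = ReadDesign(**kwargs)
    design.validate()
    if not truth.genome or not any(truth.genome.values()):
        raise InputError("truth bundle lacks genome sequence")
    rng = np.random.default_rng(design.seed)

    sites = truth.pa_sites()
    samples = [f"s{i + 1:02d}" for i in range(design.n_samples)]

    blocklist_seqs = {
        f"block{i + 1}": "".join(_random_seq(rng, 200)) for i in range(design.n_blocklist_seqs)
    }

    fastq: dict[str, list[pio.FastqRecord]] = {s: [] for s in samples}
    placements = []
    read_truth = []
    counter = 0

    def emit(sample, label, gene_id, chrom, pos, strand, insert):
        nonlocal counter
        counter += 1
        rid = f"r{counter:07d}"
        prefix = "".join(rng.choice(_BASES, size=design.prefix_len))
        raw = prefix + insert + "A" * design.tail_len + design.adapter
        raw = raw[: design.read_len]
        fastq[sample].append(pio.FastqRecord(rid, raw, "I" * len(raw)))
        read_truth.append((rid, sample, label, gene_id, chrom, pos, strand, len(insert)))
        if label != "blocklist":
            placements.append((rid, sample, chrom, pos, strand, 255))

    n_true_per_sample = len(sites) * design.reads_per_site
    ipr = design.internal_priming_rate
    n_ip_total = int(round(ipr / (1 - ipr) * n_true_per_sample)) if ipr < 1 else 0
    n_block = int(round(design.blocklist_rate * n_true_per_sample))

    for sample in samples:
        for _, row in sites.iterrows():
            for _ in range(design.reads_per_site):
                ln = int(rng.integers(design.min_insert, design.max_insert + 1))
                ins = _transcribed_insert(truth.genome, row.chrom, int(row.pos), row.strand, ln)
                emit(sample, row.label, row.gene_id, row.chrom, int(row.pos), row.strand, ins)
        if truth.decoy_sites and n_ip_total:
            for _ in range(n_ip_total):
                chrom, pos, strand = truth.decoy_sites[int(rng.integers(len(truth.decoy_sites)))]
                ln = int(rng.integers(design.min_insert, design.max_insert + 1))
                ins = _transcribed_insert(truth.genome, chrom, pos, strand, ln)
                emit(sample, "internal_priming", "", chrom, pos, strand, ins)
        for _ in range(n_block):
            src = blocklist_seqs[f"block{int(rng.integers(design.n_blocklist_seqs)) + 1}"]
            start = int(rng.integers(0, len(src) - 44))
            emit(sample, "blocklist", "", "", 0, "+", src[start : start + 44])

    placements_df = pd.DataFrame(placements, columns=pio.PLACEMENT_COLUMNS)
    truth_df = pd.DataFrame(
        read_truth,
        columns=["read_id", "sample", "label", "gene_id", "chrom", "pos", "strand", "insert_len"],
    )
    return QuantseqReads(fastq, placements_df, truth_df, blocklist_seqs)


# ---------------------------------------------------------------------------
# count tables


@dataclass
class Effect:
    """An injected expression effect.

    kind 'sex' multiplies the male mean by ``2**log2fc`` at ``age`` (all
    ages when ``age`` is None); kind 'interaction' applies ``-log2fc/2`` at
    ``age`` and ``+log2fc/2`` at ``age2`` to males, a crossover whose
    sex-by-age difference equals ``log2fc``.
    """

    gene: str
    log2fc: float
    kind: str = "sex"
    age: str | None = None
    age2: str | None = None


@dataclass
class CountDesign:
    n_genes: int = 2000
    n_reps: int = 6
    sexes: tuple[str, ...] = SEXES
    ages: tuple[str, ...] = AGES
    baseline_mean: float = 200.0
    baseline_sigma: float = 1.0
    dispersion: float = 0.05
    effects: list[Effect] = field(default_factory=list)
    batch_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2 per group")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with size = 1/dispersion (mean/size form)."""
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_count_tables(
    design: CountDesign | None = None, prefix: str = "gene", **kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one NB count table over a sex-by-age design.

    Returns (counts genes-by-samples, metadata). Batch covariates follow
    the study's small-RNA layout: replicates 1-3 are batch b1, 4-6 are b2,
    with per-gene multiplicative batch loadings of sd ``batch_strength``
    (log2) applied to b2 samples.
    """
    if design is None:
        design = CountDesign(**kwargs)
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = [f"{prefix}{i:04d}" for i in range(design.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    base = design.baseline_mean * rng.lognormal(
        -0.5 * design.baseline_sigma**2, design.baseline_sigma, size=design.n_genes
    )

    samples, meta_rows = [], []
    for sex in design.sexes:
        for age in design.ages:
            for rep in range(1, design.n_reps + 1):
                name = f"{sex}_{age}_r{rep}"
                samples.append(name)
                batch = "b1" if rep <= 3 else "b2"
                meta_rows.append((name, sex, age, rep, batch))
    meta = pd.DataFrame(meta_rows, columns=["sample", "sex", "age", "replicate", "batch"]).set_index("sample")

    lfc = np.zeros((design.n_genes, len(samples)))
    male = (meta.sex == "M").to_numpy()
    for eff in design.effects:
        if eff.gene not in gene_index:
            raise InputError(f"effect gene {eff.gene!r} not in simulated gene list")
        gi = gene_index[eff.gene]
        if eff.kind == "sex":
            mask = male if eff.age is None else male & (meta.age == eff.age).to_numpy()
            lfc[gi, mask] += eff.log2fc
        elif eff.kind == "interaction":
            lfc[gi, male & (meta.age == eff.age).to_numpy()] -= eff.log2fc / 2
            lfc[gi, male & (meta.age == eff.age2).to_numpy()] += eff.log2fc / 2
        else:
            raise InputError(f"unknown effect kind {eff.kind!r}")

    if design.batch_strength > 0:
        loadings = rng.normal(0.0, design.batch_strength, size=design.n_genes)
        b2 = (meta.batch == "b2").to_numpy()
        lfc[:, b2] += loadings[:, None]

    mu = base[:, None] * 2.0**lfc
    counts = _nb_draw(rng, mu, design.dispersion)
    return pd.DataFrame(counts, index=genes, columns=samples), meta


def simulate_study_tables(
    mrna_design: CountDesign | None = None, mirna_design: CountDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """mRNA and miRNA count tables as the study pairs them.

    The miRNA table drops the last profiled age (the small-RNA experiment
    excluded PD37) and carries a two-batch layout (replicates 1-3 vs 4-6)
    with a non-zero batch strength. Returns (mrna_counts, mrna_meta,
    mirna_counts, mirna_meta)."""
    if mrna_design is None:
        mrna_design = CountDesign()
    if mirna_design is None:
        mirna_design = CountDesign(
            n_genes=150,
            ages=AGES[:4],
            baseline_mean=500.0,
            batch_strength=0.3,
            seed=mrna_design.seed + 1,
        )
    mrna_counts, mrna_meta = simulate_count_tables(mrna_design, prefix="gene")
    mirna_counts, mirna_meta = simulate_count_tables(mirna_design, prefix="mmu-miR-")
    return mrna_counts, mrna_meta, mirna_counts, mirna_meta


# ---------------------------------------------------------------------------
# cell-type reference


PITUITARY_CELLTYPES = ("Somatotrope", "Lactotrope", "Gonadotrope", "Corticotrope", "Melanotrope")


@dataclass
class CellRefConfig:
    celltypes: tuple[str, ...] = PITUITARY_CELLTYPES
    n_genes: int = 300
    markers_per_type: int = 20
    marker_fc: float = 8.0
    cells_per_type: int = 200
    proportions: dict[str, list[float]] | None = None  # sex -> vector over celltypes
    n_bulk_per_sex: int = 6
    depth: float = 1e6
    dispersion: float = 0.05
    cell_size: float = 2.0  # NB size parameter for single-cell counts
    seed: int = 0


@dataclass
class CellReference:
    cell_expr: pd.DataFrame  # cells x genes
    labels: pd.Series  # cell -> celltype
    signature_truth: pd.DataFrame  # genes x celltypes mean profiles
    markers: dict[str, list[str]]
    bulk: pd.DataFrame  # genes x samples
    true_props: pd.DataFrame  # samples x celltypes
    bulk_meta: pd.DataFrame


def simulate_cell_reference(config: CellRefConfig | None = None, **kwargs) -> CellReference:
    """Simulate a labeled cell-by-gene reference and bulk mixtures.

    Each cell type gets a disjoint marker set expressed ``marker_fc``-fold
    above background; bulk samples are proportion-weighted mixtures of the
    type mean profiles with NB noise at the requested depth. Sex-dependent
    default proportions shift Lactotropes up in females and Somatotropes up
    in males, mimicking the endocrine cell-composition difference.
    """
    if config is None:
        config = CellRefConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    types = list(config.celltypes)
    k = len(types)

    if config.proportions is None:
        base = np.full(k, 1.0 / k)
        props = {}
        if k >= 2:
            shift = np.zeros(k)
            shift[0], shift[1] = 0.08, -0.08
            props["M"] = (base + shift) / (base + shift).sum()
            props["F"] = (base - shift) / (base - shift).sum()
        else:
            props = {"M": base, "F": base}
        proportions = {s: list(v) for s, v in props.items()}
    else:
        proportions = config.proportions
    for sex, vec in proportions.items():
        vec = np.asarray(vec, dtype=float)
        if len(vec) != k:
            raise InputError(f"proportion vector for {sex} has length {len(vec)}, expected {k}")
        if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
            raise InputError(f"proportions for {sex} must be non-negative and sum to 1 within 1e-9")

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    base_expr = rng.lognormal(2.0, 1.0, size=config.n_genes)
    sig = np.tile(base_expr[:, None], (1, k))
    markers: dict[str, list[str]] = {}
    cursor = 0
    for j, ct in enumerate(types):
        idx = np.arange(cursor, min(cursor + config.markers_per_type, config.n_genes))
        cursor += config.markers_per_type
        sig[idx, j] *= config.marker_fc
        markers[ct] = [genes[i] for i in idx]
    signature = pd.DataFrame(sig, index=genes, columns=types)

    # single cells: NB around the type mean profile
    cells, labels, rows = [], [], []
    for j, ct in enumerate(types):
        mu = np.tile(sig[:, j], (config.cells_per_type, 1))
        counts = rng.negative_binomial(
            config.cell_size, config.cell_size / (config.cell_size + mu)
        )
        for c in range(config.cells_per_type):
            cells.append(f"{ct}_c{c + 1:03d}")
            labels.append(ct)
        rows.append(counts)
    cell_expr = pd.DataFrame(np.vstack(rows), index=cells, columns=genes)
    labels = pd.Series(labels, index=cells, name="celltype")

    # bulk mixtures
    rel = sig / sig.sum(axis=0, keepdims=True)  # per-type relative profile
    bulk_cols, prop_rows, meta_rows = {}, [], []
    for sex, vec in proportions.items():
        vec = np.asarray(vec, dtype=float)
        for r in range(1, config.n_bulk_per_sex + 1):
            name = f"{sex}_bulk_r{r}"
            jitter = rng.normal(0, 0.02, size=k)
            p = np.clip(vec + jitter, 1e-3, None)
            p = p / p.sum()
            mu = config.depth * rel @ p
            bulk_cols[name] = _nb_draw(rng, mu, config.dispersion)
            prop_rows.append(pd.Series(p, index=types, name=name))
            meta_rows.append((name, sex, r))
    bulk = pd.DataFrame(bulk_cols, index=genes)
    true_props = pd.DataFrame(prop_rows)
    bulk_meta = pd.DataFrame(meta_rows, columns=["sample", "sex", "replicate"]).set_index("sample")

    return CellReference(cell_expr, labels, signature, markers, bulk, true_props, bulk_meta)
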