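# pituiseq

Analysis toolkit for 3'-end-anchored RNA-seq (QuantSeq / 3'UTR-seq) studies
of sex-biased gene expression in the postnatal mouse pituitary gland, with a
ground-truth synthetic data generator so every stage is testable end to end.

In 3'UTR-seq, each read's 3'-most aligned nucleotide marks a transcript's
polyadenylation (pA) site, so read counts are proportional to transcript
counts — but the protocol also creates two artifacts this package deals with
explicitly: read 3' ends that run through the polyA tail into the sequencing
adapter, and spurious 3' signal from oligo(dT) priming at genomically
A-rich loci (internal priming). On top of the refined annotation, the
package implements the downstream statistics of a sex-differences study
design: differential expression across postnatal ages with
unwanted-variation removal, miRNA–target anticorrelation networks,
co-expression modules, and cell-type deconvolution with cell-weighted
fold-changes.

## What it computes

**Annotation refinement (`readprep`, `pa_annotate`, `quantify`).** Reads
are trimmed by locating, from the 3' end, the earliest of an adapter match
or a polyA run that extends to the read end or into the (possibly
truncated) adapter; reads ≤ 36 nt after trimming are dropped, as are reads
sharing a 25-mer with rRNA/BC1-like blocklist sequences. Read 3'-end
placements build per-strand signal tracks in RPM units; maximal runs of
positions with cross-sample mean RPM ≥ 1 are expressed regions (ERs).
Intronic/intergenic ERs are dropped when the downstream transcribed-strand
sequence looks primable — an 18-mer with ≥ 12 A within 150 bp, a 7-mer
with ≥ 6 A within 20 bp, > 50 % A in the 20-bp window — or when they
overlap a repeat by > 20 bp. Surviving ERs map to known 3'UTRs, become
novel intronic pA features (± 5 bp), or extend a gene's 3'UTR when ≤ 5 kb
downstream. Counting assigns each placement to the single gene whose
exons/extensions/pA features contain it.

**Differential expression (`normalize_de`).** Empirical negative-control
genes (omnibus F across all sex × age groups, FDR ≥ 0.1) feed an SVD-based
estimate of unwanted-variation factors W (for batch-confounded miRNA data,
the SVD instead runs on within-group-centered log-CPM). Per gene, an NB
log-linear model with cell-means group coding, W, and log library-size
offsets is fit; contrasts (sex within age, sex-by-age interaction) are
tested by likelihood ratio with a small-sample F correction. Dispersion is
a method-of-moments estimate shrunk 50/50 toward the trimmed-mean common
value. Sex-biased calls require |FC| > 1.5 and BH FDR < 0.05.

**Networks and modules (`target_network`, `coexpress`).** Predicted
(TargetScan-style, cumulative weighted context score < −0.1) and validated
(miRTarBase-style) miRNA–target pairs with both endpoints sex-biased are
tested for Spearman anticorrelation (midranks; exact permutation p for
n ≤ 9); edges require rho < 0 at FDR < 0.1. Co-expression modules come
from average-linkage clustering on topological-overlap dissimilarity of
|cor|^β networks, with eigengenes (first PC) and top-10 connectivity hubs.

**Cell types (`celltype`).** Module genes are scored per cell type with a
one-sided two-sample KS statistic (D = sup CDF difference) against all
other cells, and modules for enrichment of KS-significant genes by
upper-tail hypergeometric tests. Bulk samples are deconvolved by
non-negative least squares against a signature of per-type mean expression
over top-variance reference genes, with simplex renormalization; sex
differences in proportions use exact Wilcoxon rank-sum tests. Finally,
cwFC(g, c) = log2FC(g) · w(g, c) · r(c) redistributes each sex-biased
gene's bulk fold-change over cell types (w = signature specificity, r =
mean estimated proportion); |gene-normalized cwFC| > 0.5 calls a gene
cell-type-specific.

**Synthetic truth (`synthetic`).** A toy genome with hidden 3'UTR
extensions, intronic pA sites, A-rich decoy loci and repeats; 3'-anchored
reads with polyA-into-adapter ends; NB count tables with injected sex/age/
interaction effects and batch structure; and a labeled multi-cell-type
reference with sex-dependent mixture proportions. Every planted signal is
written to truth tables that the tests score recovery against.

## Worked example

```python
from pituiseq import synthetic, pa_annotate, quantify, normalize_de

truth = synthetic.make_truth_genome(n_genes=30, seed=1)
reads = synthetic.simulate_quantseq_reads(truth, n_samples=10, reads_per_site=200,
                                          internal_priming_rate=0.1, seed=1)
utrs = [(g.chrom, g.utr3[0], g.utr3[1], g.gene_id) for g in truth.annotation]
aug, ers, report = pa_annotate.annotate_pa(
    reads.placements, truth.genome, truth.annotation, utrs, truth.repeats)
print("annotation refinement:", report)

cm = quantify.count_reads(reads.placements, aug)
print("counted reads:", int(cm.counts.to_numpy().sum()), "of", len(reads.placements))

effects = [synthetic.Effect(f"gene{i:04d}", 1.5, "sex", "PD27") for i in range(30)]
counts, meta = synthetic.simulate_count_tables(n_genes=2000, n_reps=6,
                                               effects=effects, seed=43)
res = normalize_de.test_differential(quantify.CountMatrix.from_counts(counts),
                                     meta, "sex@PD27")
print("sex-biased calls at PD27:", int(res.called.sum()))
```

prints

```
annotation refinement: {'genes_with_internal_pa': 9, 'genes_with_extension': 9, 'genes_with_both': 4, 'novel_ers': 18}
counted reads: 96000 of 106670
sex-biased calls at PD27: 29
```

The 30-gene genome hides 9 intronic pA sites and 9 extensions (4 genes get
both); all 18 are recovered as novel ERs, and none of the 10,670
internal-priming placements at decoy loci survives the filters (96,000
counted reads are exactly the true-site reads). Of the 30 genes injected
with a 1.5 log2 male bias, 29 are called — recall 0.97 at precision 1.00
against the generator's truth table.

A CLI covers the pipeline stages: `pituiseq simulate | trim | annotate-pa |
count | filter-expr | de` (see `pituiseq --help`).

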