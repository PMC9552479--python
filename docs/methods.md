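# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Read trimming

A 3'UTR-seq read is modeled as `prefix (12 nt) + insert + polyA tail +
adapter`, truncated to the read length (68 nt by default). Trimming must
find the insert/tail boundary even when the adapter is cut to an arbitrary
fragment by read-length truncation. The algorithm:

1. Find the leftmost adapter match: a ≥ 10-nt prefix of the adapter with
   ≤ 10 % mismatches. Failing that, the longest exact terminal adapter
   prefix fragment; fragments ≥ 5 nt count as adapter matches on their own.
2. Find the polyA run ending at the adapter start (or read end). The run
   is the score-maximizing extent scanning 5'-ward (match +1, mismatch −4)
   that keeps ≥ 90 % A content and starts on an A. The score penalty makes
   the run stop at the biological boundary instead of swallowing occasional
   genomic A's immediately upstream of the cleavage site, while still
   crossing an isolated sequencing error inside a long tail. A plain
   "maximal run with ≥ 90 % A" rule absorbs genomic `...A C` suffixes into
   the tail and caps exact boundary recovery well below the 99 % the rest
   of the pipeline assumes; the scored run was adopted for that reason.
3. Terminal adapter fragments of 1–4 nt are trimmed only when preceded by
   a qualifying polyA run — alone they are indistinguishable from genomic
   sequence, but behind a ≥ 8-A run they are unambiguous truncated adapter.
4. Remove the first 12 nt (random priming prefix); keep reads strictly
   longer than 36 nt.

Quality strings are sliced in lockstep; no quality-based trimming is done.
Blocklist filtering removes reads sharing any exact 25-mer (either strand)
with an rRNA/BC1-like sequence; k = 25 makes chance hits against a toy
genome negligible (expected collisions « 1) while matching any real
overrepresented fragment of ≥ 25 nt.

## PolyA-site discovery

Signal tracks count read 3'-most nucleotides per (sample, chromosome,
strand); RPM = count × 10⁶ / placed reads for that sample. Expressed
regions are maximal runs of positions whose cross-sample mean RPM is ≥ 1.0
(the cutoff is inclusive). Classification against gene models is
strand-agnostic and allows overlapping categories; only ERs confined to
introns/intergenic space are screened as candidate novel sites — any ER
touching an exon or UTR is left to the existing annotation.

The internal-priming screen evaluates the transcribed-strand sequence
downstream of the ER's 3' end (reverse-complemented for minus-strand ERs):
drop when (a) any 18-mer within 150 bp has ≥ 12 A, (b) any 7-mer within
20 bp has ≥ 6 A, (c) the 20-bp window is > 50 % A, or (d) the ER overlaps
an annotated repeat by > 20 bp. Rules are checked in the order a, b, c, d
and the first failure is recorded; the kept/dropped outcome is
order-independent (the label is not). Windows running past the chromosome
end are truncated and the rules evaluated on the available bases; motif
windows that no longer fit are skipped.

Assignment precedence for surviving ERs: (1) overlap with a known
(RefSeq-style) 3'UTR of a same-strand gene — counted to that gene, no
annotation change; (2) intronic within exactly one same-strand gene — a
novel internal pA feature padded 5 bp each side (two or more candidate
hosts → unassigned, reason `ambiguous_host`); (3) within 5 kb 3' of a
same-strand gene end and not inside another gene — the nearest such gene's
terminal 3'UTR and end are extended to the ER's far end, monotonically
when several ERs extend the same gene; (4) otherwise unassigned. Counting
then assigns each placement to the unique same-strand gene whose exons
(with extensions folded in) or pA features contain its 3' end; multi-gene
hits are discarded, mirroring a unique-assignment counter run at
mapping-quality 255.

## Expression filtering and normalization

CPM uses the per-sample total of assigned reads, fixed before any row
exclusion, so filtering does not change the scale. Genes with CPM
strictly > 2 in at least 10 samples are retained after dropping
mitochondrial (`mt-`) and spike-in (`ERCC-`) identifiers.

Negative-control genes are those with no omnibus evidence of any condition
effect: a vectorized one-way F test across all sex × age groups on log2
CPM (prior count 0.5), BH-adjusted, controls = FDR ≥ 0.1. The F statistic
for a zero-variance gene is defined as 0, so constant genes are always
controls. An ordinary rather than variance-moderated F is used; at the
replicate counts this package targets (n ≥ 4 per group) moderation changes
the control set marginally and the downstream factor estimates not at all.

Unwanted-variation factors are the leading left singular vectors of
centered log-CPM: centered per gene over samples when restricted to
control genes (control-gene mode), or centered within sex × age replicate
groups over all genes (replicate-group mode, which removes biology by
construction and is the batch treatment for the two-batch small-RNA
design). k = 1 by default — the smallest correction; raise it only with
evidence of multiple technical axes.

## Differential testing

Counts are modeled per gene as NB with log link, cell-means coding of the
sex × age groups, the W factors as covariates, and log library-size
offsets. Dispersion (variance = μ + αμ²) is estimated by method of
moments within groups on depth-scaled counts, pooled with
degrees-of-freedom weights, clipped to [10⁻⁴, 10], and shrunk 50/50 toward
the 20 %-trimmed mean across genes. Fitting is IRLS vectorized across
genes (shared design, batched normal equations, ridge 10⁻⁸, η clipped to
± 30); non-converged genes are flagged and assigned p = 1.

A contrast (sex difference at one age, or the difference of sex
differences between two ages) is tested by likelihood ratio between the
full model and the design restricted to the contrast's null space. The
1-df statistic is referred to F(1, N − p) rather than χ²(1): with n = 6
per group the χ² reference is visibly anticonservative (measured as called
false positives beyond the BH level), and the F reference restores
calibration — measured null behavior is ~1 call-bearing simulation in 60
at BH 0.05 with the 1.5-fold filter. log2 fold-changes are raw fitted
coefficients (no shrinkage); positive = male-biased. BH adjustment is
applied within each contrast separately. Calls: FDR < 0.05 and |FC| > 1.5
for sex contrasts; FDR < 0.05 alone for interactions.

## miRNA handling

The small-RNA length window is exact: 18 ≤ length ≤ 22 nt after adapter
trimming. Batch correction reuses the replicate-group factor mode with
k = 1. A precursor is a mirtron iff it lies fully inside one intron of a
same-strand gene and touches no exon of any gene; the intron ordinal is
reported in transcription direction ("last" for the terminal intron).
Precursors overlapping gene bodies without touching exons but failing the
mirtron condition (antisense, boundary-crossing) are grouped with
intergenic — they are not splicing products.

## Target network

Predicted pairs require cumulative weighted context score strictly below
−0.1; validated pairs carry no score. Only pairs whose miRNA and gene are
each sex-biased at some profiled age are tested, on samples matched by ID
between the mRNA and miRNA tables (≥ 5 required). Spearman's rho uses
midranks; p-values are exact (full permutation enumeration) for n ≤ 9 and
t-approximate otherwise. BH runs over tested pairs only; edges need
rho < 0 and FDR < 0.1. Constant expression vectors make rho undefined —
such pairs are skipped with a recorded reason rather than given a value.

## Co-expression modules

The variance filter fits an inverse-gamma distribution to per-gene sample
variances by maximum likelihood (location fixed at 0) and keeps genes in
the upper tail at p < 0.1; a degenerate fit falls back to the top variance
decile with a warning. The network is unsigned: adjacency = |Pearson
r|^β. β is the smallest integer in 1..20 whose binned log-log connectivity
distribution fits a line with R² ≥ 0.8; when nothing reaches the target
(typical for small or block-structured networks, where the scale-free
criterion is ill-posed) the conventional unsigned default β = 6 is used —
chasing the best-fitting exponent instead drives β high enough to wash out
within-module similarity. Genes are clustered by average linkage on
1 − TOM (topological overlap) and the tree is cut at 0.99 of the maximum
merge height; clusters under the minimum size (default 30; tests use
smaller) become module 0 (unassigned). This fixed-height-plus-size-floor
cut is this package's simplified stand-in for dynamic hybrid tree cutting;
it recovers planted block structure exactly and sends uncorrelated genes
to module 0, but will not reproduce the reference procedure's adaptive
splits on deeply nested dendrograms. Eigengenes are first principal
components of module-scaled expression, sign-aligned with the module mean;
hubs are the top 10 genes by within-module adjacency row sum.

## Cell-type analyses

The one-sided KS statistic is D = sup over the pooled sample points of
(CDF_others − CDF_in-type); its p-value is the one-sided asymptotic tail
exp(−2D²nm/(n+m)), adequate at the ≥ 20 cells per type this module
requires. FDR pools all gene × type tests. Module enrichment uses the
upper-tail hypergeometric with universe = all KS-tested module genes.

The signature matrix is per-type mean CPM over the reference's top-3000
variance genes (300 at toy scale); deconvolution solves non-negative least
squares on CPM vectors over shared genes and renormalizes to the simplex.
Wilcoxon rank-sum tests on proportions are exact and two-sided, switching
to midranks with the normal approximation under ties (flagged in the
output); p-values are reported raw, matching per-age star annotations
rather than a multiplicity-adjusted table.

cwFC: specificity w(g,c) is the gene's signature row normalized to sum 1;
the proportion factor r(c) averages the two sexes' mean estimated
proportions; cwfc = log2FC · w · r, gene-normalized by total |cwfc|, with
|cwfc_norm| > 0.5 calling a cell type. Sign therefore always matches the
bulk fold-change, a gene expressed in one type gets |cwfc_norm| = 1, and a
gene spread evenly over four types gets 0.25 everywhere and is never
called. This closed-form reweighting deliberately omits the false-positive
flagging and outlier-assignment heuristics of more elaborate cwFC tools.

## Synthetic data: what it does and does not emulate

The generator plants all ground truth explicitly: gene models with one
intron, hidden 3'UTR extensions 300–1500 bp downstream, intronic pA sites,
A-rich decoy loci (70 % A over 20 bp downstream of the decoy site), and
repeat intervals. True pA sites get downstream sequence re-sampled until
it passes the internal-priming screen and a fixed C at the cleavage
position — a genuine site is, by the filter's own definition, one without
primable downstream context, and the pinned base makes the insert/tail
boundary exact so trimming is scored against an unambiguous truth. Reads
are built exactly as the trimming model assumes (12-nt random prefix,
38–48-nt insert, 10-A tail, adapter, truncation to 68 nt) with exact
placement positions and mapq 255.

Count tables are NB in mean/size form (size = 1/dispersion, dispersion
0.05, baseline mean 200 with log-normal spread σ = 1) over 2 sexes × 5
postnatal ages × 6 replicates; effects multiply group means by 2^log2FC;
the miRNA design drops the last age and adds a two-batch structure
(replicates 1–3 vs 4–6) with per-gene log-normal batch loadings. The cell
reference uses five pituitary cell types with disjoint 20-gene marker sets
8-fold above background, NB single-cell noise, and bulk mixtures whose
sex-dependent proportions shift somatotropes up in males and lactotropes
up in females by 0.08.

Not emulated: sequencing errors beyond none (uniform-substitution hooks
exist in principle but default off), UMIs/duplicates, splicing-aware reads,
multi-mapping, chimeric artifacts, depth variation across samples, and
correlated gene-gene structure outside the co-expression benchmarks.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration under the declared generative model, not
robustness to alignment noise or real library pathologies.

Benchmark scales were chosen to keep each stage's check direct: 30 genes /
10 samples / 200 reads per site for pA recovery; 2,000 genes × 12 groups ×
6 replicates × 20 simulations for calibration; 10 seeds for interaction
and module recovery; 50 mixtures at depth 10⁶ for deconvolution. The
deconvolution mixture benchmark uses technical-replicate overdispersion
(0.01): it is a mixing experiment isolating the regression step, whereas
the generator's bulk samples carry biological dispersion (0.05), for which
proportion error is bounded by biology rather than depth (~0.02–0.03 even
with the true signature).

## Known limitations

- The ER-to-gene assignment cannot distinguish an intronic pA of one gene
  from a 3'UTR extension of an upstream neighbor when geometry permits
  both; the precedence order above is this package's explicit rule.
- The fixed-height module cut under-splits nested correlation structure;
  β selection on small gene sets rarely satisfies the scale-free criterion
  and then uses the documented default.
- Exact Spearman permutation p-values are limited to n ≤ 9 (9! ≈ 3.6 × 10⁵
  permutations per pair); above that the t approximation is used.
- The NB engine shares one design across genes; per-gene covariates (e.g.
  gene-specific offsets beyond library size) are out of scope.
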