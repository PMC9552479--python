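import pytest

from pituiseq import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A 12-gene toy genome with extensions, intronic sites and decoys."""
    return synthetic.make_truth_genome(
        n_genes=12, frac_extensions=0.5, frac_intronic_pa=0.5, n_decoys=4, seed=7
    )


@pytest.fixture(scope="session")
def small_reads(small_truth):
    """Reads for the small genome: 3 samples, 50 reads/site."""
    return synthetic.simulate_quantseq_reads(
        small_truth, n_samples=3, reads_per_site=50, internal_priming_rate=0.1, seed=7
    )


@pytest.fixture(scope="session")
def refseq_utrs(small_truth):
    return [
        (g.chrom, g.utr3[0], g.utr3[1], g.gene_id) for g in small_truth.annotation if g.utr3
    ]


@pytest.fixture(scope="session")
def cell_reference():
    return synthetic.simulate_cell_reference(seed=2)
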