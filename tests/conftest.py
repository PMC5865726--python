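import numpy as np
import pytest

from rapscan.core import ChromSizes, Feature, GenomicInterval


@pytest.fixture
def small_sizes():
    return ChromSizes({"chrI": 10_000, "chrII": 6_000})


@pytest.fixture
def small_genes(small_sizes):
    return [
        Feature(GenomicInterval("chrI", 500, 2_000, "+"), "ORF", "geneA"),
        Feature(GenomicInterval("chrI", 3_000, 5_500, "-"), "ORF", "geneB"),
        Feature(GenomicInterval("chrII", 1_000, 4_000, "+"), "ORF", "geneC"),
    ]


def occupancy_cohort(n_genes, seed, min_len=1500, max_len=5000, median_len=2500):
    """A single-chromosome cohort of long genes with 200-nt gaps, for the
    Pol II occupancy analyses (trimmed bodies must hold RAPs plus flanks)."""
    rng = np.random.default_rng(seed)
    feats = []
    cursor = 500
    for i in range(n_genes):
        length = int(np.clip(rng.lognormal(np.log(median_len), 0.3), min_len, max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(
            Feature(GenomicInterval("chr1", cursor, cursor + length, strand), "ORF", f"g{i:04d}")
        )
        cursor += length + 200
    return ChromSizes({"chr1": cursor + 500}), feats
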