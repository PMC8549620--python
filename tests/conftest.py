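import numpy as np
import pytest

from introscan.types import GeneAnnotation, HaplotypePanel


def make_panel(hap_matrix, positions=None, chrom="chr1", phased=True):
    """Small phased panel from a (n_hap, n_snps) 0/1 matrix."""
    hap = np.asarray(hap_matrix, dtype=np.int8)
    n_hap, n_snps = hap.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 1000
    return HaplotypePanel(
        chrom=np.full(n_snps, chrom, dtype=object),
        pos_bp=np.asarray(positions),
        alleles=np.array([("A", "T")] * n_snps, dtype=object),
        hap_matrix=hap,
        sample_ids=[f"s{i}" for i in range(n_hap // 2)],
        phased=phased,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_panel(rng):
    """60 haplotypes x 40 independent SNPs with intermediate frequencies."""
    freqs = rng.uniform(0.2, 0.8, size=40)
    hap = (rng.random((60, 40)) < freqs).astype(np.int8)
    return make_panel(hap)


@pytest.fixture
def gene_set():
    return [
        GeneAnnotation("pc1", "chr1", 100_000, 150_000, "protein_coding"),
        GeneAnnotation("lnc1", "chr1", 140_000, 210_000, "lncRNA"),
        GeneAnnotation("pc2", "chr1", 500_000, 520_000, "protein_coding"),
        GeneAnnotation("pc3", "chr2", 1_000, 5_000, "protein_coding"),
        GeneAnnotation("oth1", "chr1", 300_000, 310_000, "other"),
    ]
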