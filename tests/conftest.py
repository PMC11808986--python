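import numpy as np
import pytest
import scipy.sparse as sp

from loopscape.core_io import ContactMatrix, GenomicInterval, Loop


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_contact_matrix(rng, n_bins=50, resolution=5000, density=0.3, chrom="chr1"):
    """Random sparse symmetric contact matrix (upper triangle stored)."""
    dense = np.zeros((n_bins, n_bins))
    iu = np.triu_indices(n_bins)
    vals = rng.poisson(5.0, size=len(iu[0])).astype(float)
    vals[rng.random(len(vals)) > density] = 0.0
    dense[iu] = vals
    return ContactMatrix(
        chrom=chrom, resolution=resolution, n_bins=n_bins,
        counts=sp.csr_matrix(np.triu(dense)),
    )


@pytest.fixture
def small_loop():
    return Loop(
        "L1",
        GenomicInterval("chr1", 100_000, 105_000),
        GenomicInterval("chr1", 200_000, 205_000),
    )
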