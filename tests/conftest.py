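import numpy as np
import pytest

from bactx.core import DetectionConfig, FeatureRecord, GenomeAnnotation
from bactx.profiles import StrandProfile


@pytest.fixture
def config():
    return DetectionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_profile(length, starts_fwd=(), starts_rev=(), cov_fwd=(), cov_rev=(), total=None):
    """Build a StrandProfile from sparse (position, count) pairs."""
    prof = StrandProfile.zeros(length, total_mapped_reads=0)
    for pos, c in starts_fwd:
        prof.read_starts_fwd[pos] += c
    for pos, c in starts_rev:
        prof.read_starts_rev[pos] += c
    for pos, c in cov_fwd:
        prof.coverage_fwd[pos] += c
    for pos, c in cov_rev:
        prof.coverage_rev[pos] += c
    prof.total_mapped_reads = (
        total
        if total is not None
        else max(1, int(prof.read_starts_fwd.sum() + prof.read_starts_rev.sum()))
    )
    return prof


@pytest.fixture
def two_gene_annotation():
    """A 2 kb genome: forward CDS at [500, 800), reverse CDS at [1200, 1500)."""
    seq = "A" * 2000
    return GenomeAnnotation(
        "chr",
        seq,
        [
            FeatureRecord("geneF", "CDS", 500, 800, "+"),
            FeatureRecord("geneR", "CDS", 1200, 1500, "-"),
        ],
    )
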