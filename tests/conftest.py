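import numpy as np
import pytest

from msinmd.gene_models import GenomeSequence, TranscriptModel
from msinmd.synthetic_cohort import SyntheticCohortParams, generate_gene_models


def make_gene(
    chrom_seq,
    exons,
    strand="+",
    cds_start=0,
    cds_end=None,
    tid="t1",
    gid="g1",
    chrom="chr1",
):
    """Hand-built transcript + genome for small worked examples."""
    if cds_end is None:
        cds_end = sum(e - s for s, e in exons)
    model = TranscriptModel(tid, gid, chrom, strand, tuple(exons), cds_start, cds_end)
    return model, GenomeSequence({chrom: chrom_seq})


@pytest.fixture(scope="session")
def small_params():
    return SyntheticCohortParams(
        n_genes=40,
        n_msi_samples=8,
        n_mss_samples=8,
        n_normal_samples=8,
        fraction_le_repeats=0.2,
        fraction_intronic_repeats=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_set(small_params):
    """A 40-gene model set shared across read-only tests."""
    return generate_gene_models(small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
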