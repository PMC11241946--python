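import numpy as np
import pytest

from regmark.model import GeneModel, GenomicInterval, Peak, Transcript


def make_gene(gene_id, chrom, start, end, strand="+", exons=None):
    """Single-transcript gene; exons default to the full span."""
    exons = exons or [(start, end)]
    return GeneModel(
        gene_id,
        (
            Transcript(
                f"{gene_id}.t1",
                GenomicInterval(chrom, start, end, strand),
                tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
            ),
        ),
    )


def make_peak(chrom, start, end, mark="H3K4me1", sample="s1", **kw):
    return Peak(GenomicInterval(chrom, start, end), mark, sample, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset shared by the heavier integration tests."""
    from regmark.simulate import SimulationConfig, generate

    return generate(SimulationConfig(seed=7))
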