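import pytest

from tfdirect.genomic_io import GeneModel, GenomicInterval, Peak


@pytest.fixture
def plus_gene():
    return GeneModel(
        "GENEP", "genep", GenomicInterval("chr1", 10_000, 16_000, "+"),
        (GenomicInterval("chr1", 10_000, 10_400, "+"),
         GenomicInterval("chr1", 12_000, 12_600, "+")),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        "GENEM", "genem", GenomicInterval("chr1", 40_000, 47_000, "-"),
        (GenomicInterval("chr1", 46_500, 47_000, "-"),),
    )


@pytest.fixture
def peak_at():
    def make(summit, width=400, chrom="chr1"):
        start = max(0, summit - width // 2)
        return Peak(GenomicInterval(chrom, start, start + width), summit - start)

    return make


@pytest.fixture(scope="session")
def sim_noiseless(tmp_path_factory):
    """One zero-noise synthetic study shared across tests (seeded)."""
    from tfdirect.synthetic import simulate_dataset

    outdir = tmp_path_factory.mktemp("sim_noiseless")
    truth = simulate_dataset(outdir, seed=11, effect_sd=0.0, null_sd=0.0)
    return outdir, truth
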