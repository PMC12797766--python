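import pytest

from pb10x.design import select_barcodes
from pb10x.plate import make_layout
from pb10x.resources import toy_whitelist
from pb10x.simulate import make_transcriptome, simulate_expression, simulate_reads


@pytest.fixture(scope="session")
def whitelist():
    return toy_whitelist(n=500, seed=1)


@pytest.fixture(scope="session")
def barcodes24(whitelist):
    return select_barcodes(whitelist, n=24, d_min=5).barcodes


@pytest.fixture(scope="session")
def layout24(barcodes24):
    return make_layout(barcodes24, n_cells=24, pool_size=24)


@pytest.fixture(scope="session")
def transcriptome():
    return make_transcriptome(n_genes=60, mito_fraction=0.1, seed=2)


@pytest.fixture(scope="session")
def expression(layout24, transcriptome):
    return simulate_expression(layout24, transcriptome, mean=5.0, dispersion=2.0, seed=3)


@pytest.fixture(scope="session")
def clean_sim(expression, layout24, transcriptome):
    """Error-free, artifact-free simulation: 24 cells x 100 reads."""
    return simulate_reads(
        expression,
        layout24,
        depth_per_cell=100,
        seed=7,
        transcriptome=make_transcriptome(n_genes=60, mito_fraction=0.1, seed=2),
    )


@pytest.fixture(scope="session")
def artifact_sim(expression, layout24):
    """Simulation with 10% concatemers and 20% strand invasion."""
    return simulate_reads(
        expression,
        layout24,
        depth_per_cell=420,
        concatemer_rate=0.10,
        invasion_rate=0.20,
        seed=4,
        transcriptome=make_transcriptome(n_genes=60, mito_fraction=0.1, seed=2),
    )
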