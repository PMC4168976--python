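import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tifa import pipeline, synthetic

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_library():
    """A 400 kb circular genome with 300 genes and a saturating library."""
    art = synthetic.generate_genome(seed=7, length=400_000, ta_density=0.04,
                                    n_genes=300)
    records, truth = synthetic.generate_library(art, seed=8, m_colonies=8000)
    ds = pipeline.prepare(art.seq, True, art.genes, records, art.operons)
    return art, records, truth, ds


@pytest.fixture(scope="session")
def small_result(small_library):
    _, _, _, ds = small_library
    return pipeline.run_pipeline(ds, window=20_000, step=4_000)


@pytest.fixture(scope="session")
def paper_library():
    """Full study-scale dataset: 5 Mb, 4200 genes, 40k colonies, planted bias."""
    P = synthetic.PAPER_SCALE
    art = synthetic.generate_genome(seed=1, length=P["length"],
                                    ta_density=P["ta_density"],
                                    n_genes=P["n_genes"])
    records, truth = synthetic.generate_library(
        art, seed=2, loc_coeffs=P["loc_coeffs"],
        motif_spread=P["motif_spread"], rho=P["rho"],
        m_colonies=P["m_colonies"], non_ta_rate=P["non_ta_rate"])
    ds = pipeline.prepare(art.seq, True, art.genes, records, art.operons)
    return art, truth, ds


@pytest.fixture(scope="session")
def paper_result(paper_library):
    _, _, ds = paper_library
    return pipeline.run_pipeline(ds)
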