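import numpy as np
import pytest

from atacre import SyntheticDesign, pipeline
from atacre.synthetic import generate_all


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline run on the default synthetic design (shared: the
    generators and the run are deterministic under the design seed)."""
    return pipeline.run_end_to_end(SyntheticDesign())


@pytest.fixture(scope="session")
def small_bundle():
    """Quick bundle for structural checks (reduced depth and counts)."""
    design = SyntheticDesign(
        genome_length=500_000,
        n_genes=40,
        n_accessible_regions=60,
        depth=40_000,
        array_n_proteins=100,
    )
    return generate_all(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
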