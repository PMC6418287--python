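import numpy as np
import pytest

from cnaphase import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20190314)


@pytest.fixture(scope="session")
def small_genome():
    """A compact two-chromosome genome for fast patient simulations."""
    return (("1", 60_000_000), ("2", 40_000_000))


@pytest.fixture(scope="session")
def clean_patient(small_genome):
    """A simulated patient with parameters benign to every filter:
    deep coverage, high somatic VAFs, perfect trunk detection."""
    cfg = simulate.SimulationConfig(
        seed=101, n_patients=1, tumors_per_patient=2, regions_per_tumor=2,
        purity_per_region=0.8, mean_depth=100.0, het_site_density=2.0,
        genome=small_genome,
        somatic_params=simulate.SomaticParams(
            trunk_mutations_per_tumor=20, private_mutations_per_region=5,
            trunk_detection_prob=1.0, cross_tumor_shared=0,
            vaf_distribution=(0.4, 80.0)),
    )
    return cfg, simulate.simulate_patient(cfg, 0)
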