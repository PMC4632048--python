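import numpy as np
import pytest
from hypothesis import settings

from beanchip import synthetic

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def small_genome():
    """Two chromosomes, a handful of scaffolds — enough for truth checks."""
    return synthetic.simulate_genome(
        n_chromosomes=2,
        scaffold_length_model={"n_scaffolds": 6, "mean_log_bp": np.log(30_000.0), "sigma_log": 0.4},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return synthetic.simulate_panel(small_genome, snp_density=0.002, seed=12)


@pytest.fixture(scope="session")
def small_f2(small_genome, small_panel):
    true_map = synthetic.true_map_from_genome(small_panel, small_genome)
    return synthetic.simulate_f2(
        small_panel, "var_01", "var_02", true_map, n_plants=150, seed=13
    )
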