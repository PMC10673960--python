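import numpy as np
import pytest

from snailqtl.sim import CrossConfig, TraitLocus, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """A modest 3-group cross with one fully penetrant locus per outer group."""
    config = CrossConfig(
        seed=42,
        lg_lengths_cm=[60.0, 50.0, 60.0],
        markers_per_lg=[50, 40, 50],
        n_offspring=75,
        genotyping_error=0.002,
        missing_rate=0.05,
    )
    loci = [
        TraitLocus("C", lg=1, cm_pos=30.0, dominant_phenotype=0),
        TraitLocus("U", lg=3, cm_pos=25.0, dominant_phenotype=1),
    ]
    return simulate_cross(config, loci), config, loci


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
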