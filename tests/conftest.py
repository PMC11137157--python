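import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")

import csslmap as cm


@pytest.fixture(scope="session")
def small_map():
    """Three 5-Mb / 100-cM chromosomes."""
    return cm.make_genetic_map([("chr01", 5_000_000, 100.0),
                                ("chr02", 5_000_000, 100.0),
                                ("chr03", 5_000_000, 100.0)])


@pytest.fixture(scope="session")
def small_population(small_map):
    cfg = cm.SimConfig(n_lines=40, n_backcross=2, n_self=3, seed=123)
    return cm.simulate_cssl_population(small_map, cfg)


@pytest.fixture(scope="session")
def small_markers(small_map, small_population):
    rng = np.random.default_rng(124)
    return cm.genotype_markers(small_population, small_map, 200,
                               error_rate=0.005, missing_rate=0.02, rng=rng)


@pytest.fixture(scope="session")
def annotation_fixture():
    return cm.make_annotation_fixture(cm.FixtureConfig(), np.random.default_rng(9))
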