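import numpy as np
import pytest

from histotriage import Cohort, CohortConfig, GeneSpec, generate_cohort


@pytest.fixture(scope="session")
def scored_cohort() -> Cohort:
    """1000-slide, 10-site cohort with calibrated binormal slide scores."""
    cfg = CohortConfig(
        n_sites=10, slides_per_site=100,
        genes=[GeneSpec("TP53", 0.35, 0.79), GeneSpec("CDH1", 0.12, 0.72)],
        seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiled_cohort() -> Cohort:
    """Small cohort carrying tile scores and 4-d tile features."""
    cfg = CohortConfig(
        n_sites=8, slides_per_site=25,
        genes=[GeneSpec("KRAS", 0.4, 0.5)],
        tiles_per_slide=30, signal_tile_fraction=0.1, feature_dim=4,
        seed=202)
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
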