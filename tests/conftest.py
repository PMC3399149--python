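import numpy as np
import pytest

from flaxpopgen.synthetic_data import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study: 4 loci, one wild + two domesticated groups."""
    cfg = StudyConfig(
        locus_lengths={"L1": 300, "L2": 250, "L3": 200, "L4": 350},
        wild_size=8,
        group_sizes={"dehiscent": 6, "oil": 6},
        alpha_per_group={"dehiscent": 1.5, "oil": 3.0},
        theta_wild_per_site=0.01,
        seed=11,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The full study-shaped dataset: 24 loci, 48 samples, 5 groups."""
    return generate_study(StudyConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
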