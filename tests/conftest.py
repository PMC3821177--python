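import numpy as np
import pytest
from hypothesis import settings

from pvstereo.synthetic import CohortConfig

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_cohort_config():
    """A cohort at reduced sampling scale for fast structural tests.

    Statistical defaults (baseline, slope, noise) are the standard study
    conditions; only the per-animal sampling effort is reduced.
    """
    return CohortConfig(
        n_sections=4,
        disectors_per_animal=8,
        scene_xy_um=1600.0,
        seed=11,
    )
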