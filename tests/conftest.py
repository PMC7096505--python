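import numpy as np
import pytest

from ecmir.hyperio import WavenumberAxis
from ecmir.synthcohort import SynthCohortConfig


@pytest.fixture(scope="session")
def axis_default() -> WavenumberAxis:
    """The full measured range: 750–2000 cm⁻¹ at 2 cm⁻¹ spacing."""
    return WavenumberAxis.from_range(750.0, 2000.0, 2.0)


@pytest.fixture(scope="session")
def small_synth_config() -> SynthCohortConfig:
    """A reduced cohort for fast pipeline-level tests."""
    return SynthCohortConfig(n_ecm3=6, n_non_ecm3=6, image_shape=(24, 24))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
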