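import numpy as np
import pytest

from contactburst.synthetic import StudyConfig, gen_full_study


@pytest.fixture(scope="session")
def small_phenom_study():
    """Compact phenomenological study reused by read-only tests."""
    cfg = StudyConfig(seed=11, n_lines=60, fish_cells=150)
    return gen_full_study(cfg)


@pytest.fixture(scope="session")
def small_apparent_study():
    cfg = StudyConfig(seed=12, n_lines=60, fish_cells=150, model="apparent")
    return gen_full_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
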