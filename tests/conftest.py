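import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    """Two replicates (T=4 and T=3) over three genes, continuous values."""
    from boostgrn import TimeCourseDataset

    gen = np.random.default_rng(7)
    return TimeCourseDataset(
        gene_names=["G1", "G2", "G3"],
        replicates=[gen.standard_normal((4, 3)), gen.standard_normal((3, 3))],
    )
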