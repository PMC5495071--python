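import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_annotation():
    from gutreg.formats import GeneRecord

    return [
        GeneRecord("g1", "chr1", "+", 4000),
        GeneRecord("g2", "chr1", "-", 20000),
        GeneRecord("g3", "chr2", "+", 1000),
    ]
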