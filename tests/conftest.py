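import pytest
from hypothesis import HealthCheck, settings

from exerprog import build_grid, demo_catalog

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def full_grid():
    """Grid with two games in every one of the 36 sub-categories."""
    return build_grid(demo_catalog())


@pytest.fixture(scope="session")
def memory_gap_grid():
    """Grid emulating a catalog with no memory-domain games (9 empty cells)."""
    return build_grid(demo_catalog(include_memory=False))
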