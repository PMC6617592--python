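import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swardscan import FieldConfig, ScanStream

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_config() -> FieldConfig:
    """Five 2 m plots on a 10 m column; otherwise the stock parameters."""
    return FieldConfig(scan_length_mm=10_000.0, segments_per_scan=5)


@pytest.fixture
def make_stream():
    """Factory for hand-built streams: make_stream(odometer, lateral, heights)."""

    def _make(odometer, lateral, heights, **kwargs) -> ScanStream:
        return ScanStream(np.asarray(lateral, float),
                          np.asarray(odometer, float),
                          np.asarray(heights, float), **kwargs)

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_922)
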