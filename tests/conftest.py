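import numpy as np
import pytest

from ppgdenoise import evaluate as ev
from ppgdenoise.signal_core import Segment


@pytest.fixture(scope="session")
def clean_segments():
    """Eight clean normalized 6 s segments at 50 Hz (shared, read-only)."""
    return ev.make_clean_segments(8, seed=42)


@pytest.fixture(scope="session")
def clean_segment(clean_segments):
    return clean_segments[0]


def make_unit_segment(values: np.ndarray, fs: float = 50.0) -> Segment:
    """Wrap raw unit-range values in a Segment (any length)."""
    values = np.asarray(values, dtype=np.float64)
    return Segment(values, fs, duration=len(values) / fs, range_tag="unit")


def make_signed_segment(values: np.ndarray, fs: float = 50.0) -> Segment:
    values = np.asarray(values, dtype=np.float64)
    return Segment(values, fs, duration=len(values) / fs,
                   range_tag="signed_unit")


@pytest.fixture
def unit_segment_factory():
    return make_unit_segment


@pytest.fixture
def signed_segment_factory():
    return make_signed_segment
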