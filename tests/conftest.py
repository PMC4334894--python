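import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from himap.genome_core import CB4, GenomicInterval
from himap.marker_genotyping import Marker, MarkerPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mb_panel():
    """Seven markers at 1..7 Mb midpoints on chromosome I (spec-style toy panel)."""
    return MarkerPanel(
        Marker(f"I-{i}", "I", i * 1_000_000 - 200, i * 1_000_000 + 200)
        for i in range(1, 8)
    )


@pytest.fixture
def cb4():
    return CB4
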