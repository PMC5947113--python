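import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from rootmru.root_model import RootAxis, RootSystem
from rootmru.synthetic_data import example_system

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_mru_system() -> RootSystem:
    """Hand-built two-MRU system whose trait vector is known by hand.

    MRU-A: main 8 cm bearing laterals of 2 cm @ 1 cm, 1.5 cm @ 3 cm (the
    latter carrying one 0.4 cm secondary lateral) and 0.3 cm @ 7 cm.
    MRU-B: bare main of 5 cm.
    """
    axes = [
        RootAxis(id="A", order=1, length=8.0),
        RootAxis(id="A1", order=2, length=2.0, parent_id="A", insertion_pos=1.0),
        RootAxis(id="A2", order=2, length=1.5, parent_id="A", insertion_pos=3.0),
        RootAxis(id="A2s", order=3, length=0.4, parent_id="A2", insertion_pos=0.5),
        RootAxis(id="A3", order=2, length=0.3, parent_id="A", insertion_pos=7.0),
        RootAxis(id="B", order=1, length=5.0),
    ]
    return RootSystem(plant_id="hand", accession="hand", axes=axes)


@pytest.fixture
def three_mru_system() -> RootSystem:
    return example_system()
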