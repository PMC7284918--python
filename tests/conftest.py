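import pytest

from gutpass.simulate import geometry_preset


@pytest.fixture
def epi_geometry():
    """EpiIntestinal 24-well insert: 0.6 cm², 100 µL apical / 5000 µL basal."""
    return geometry_preset("EpiIntestinal-24")


@pytest.fixture
def geometry_96():
    return geometry_preset("96-well")
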