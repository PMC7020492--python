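import pytest

from leafsim.energy_budget import LeafTraits, WeatherRecord
from leafsim.pasture_model import PastureParams


@pytest.fixture
def grass_traits() -> LeafTraits:
    """Narrow amphistomatous grass leaf (5 mm max width)."""
    return LeafTraits(max_leaf_width=0.005)


@pytest.fixture
def params() -> PastureParams:
    return PastureParams()


@pytest.fixture
def chamber_record():
    """Factory for chamber forcing at the standard lamp/fan settings."""

    def make(t_air: float, rh: float = 70.0, gs: float | None = None) -> WeatherRecord:
        return WeatherRecord(t_air=t_air, rh=rh, ppfd=900.0, wind=2.0)

    return make
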