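import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popcode.decoding import DecoderSpec
from popcode.encoding import PopulationParams
from popcode.spectra import NoiseSpec, default_grid, make_frequency_grid

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def pop():
    """Study-condition population: fitted tuning defaults, 100 neurons."""
    return PopulationParams.paper_defaults()


@pytest.fixture(scope="session")
def decoder():
    return DecoderSpec(width=4.2, efficiency=1.0)


@pytest.fixture(scope="session")
def noise():
    return {k: NoiseSpec(k) for k in ("none", "broadband", "lowpass",
                                      "highpass", "notched")}
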