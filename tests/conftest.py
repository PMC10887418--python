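import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import settings as hyp_settings, HealthCheck

hyp_settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("ci")

from nanomech import SampleClass, SampleClassSettings
from nanomech import synthetic as syn


@pytest.fixture(scope="session")
def cell_settings():
    return SampleClassSettings(sample_class=SampleClass.CELL_2D)


@pytest.fixture(scope="session")
def cryo_settings():
    return SampleClassSettings(sample_class=SampleClass.CRYOSECTION)


@pytest.fixture(scope="session")
def hsr_settings():
    return SampleClassSettings(sample_class=SampleClass.HSR_WHOLE)


@pytest.fixture(scope="session")
def noiseless_cell_curve(cell_settings):
    return syn.simulate_curve(4e3, cell_settings, contact_index=700)
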