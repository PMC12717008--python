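import pytest
from hypothesis import HealthCheck, settings

import ferrotrace as ft

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Full 52-participant trial with the measurement noise switched off."""
    return ft.run_end_to_end(ft.RunConfig(seed=3, noise_sd_rel=0.0))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Full 52-participant trial under the default noise model."""
    return ft.run_end_to_end(ft.RunConfig(seed=1))
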