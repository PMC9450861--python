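import pytest

from reflexfes import GaitModelParams, SpeedProtocol, generate_protocol


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free generator parameters (deterministic signals)."""
    return GaitModelParams(noise_sd_force=0.0, noise_sd_angle=0.0)


@pytest.fixture(scope="session")
def small_session(clean_params):
    """Noise-free 10-cycle session: 1.0->1.4->1.0 km/h, 2 cycles/level."""
    protocol = SpeedProtocol(1.0, 1.4, 0.2, cycles_per_level=2)
    return generate_protocol(protocol, clean_params, seed=11)
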