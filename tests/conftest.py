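import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beam():
    from beamvalid import BeamModelParams

    return BeamModelParams()


@pytest.fixture(scope="session")
def paper_protocol_config():
    """The published validation request: 5 square fields, 5 profile depths,
    depth + inline + crossline scans plus diagonals for 28x28."""
    from beamvalid import ProtocolConfig

    return ProtocolConfig()


@pytest.fixture()
def small_run_config():
    """A one-field, one-depth, crossline-only closed-loop configuration
    with zero noise, small enough for CLI round trips."""
    from beamvalid import NoiseModel, ProtocolConfig
    from beamvalid.config import ValidationRunConfig

    proto = ProtocolConfig(
        field_sizes_cm=(10.0,),
        profile_depths_cm=(10.0,),
        axes=("depth", "crossline"),
        diagonal_field_sizes_cm=(),
    )
    return ValidationRunConfig(protocol=proto, noise=NoiseModel.none())
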