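import pytest

from drivegates import DriveParams, InductionSettings, ModelVariant, SimulationConfig


@pytest.fixture
def sample_params() -> DriveParams:
    """The highlighted phase-diagram sample point: e_W = 0.8, f = 0.7."""
    return DriveParams(e_W=0.8, f=0.7)


@pytest.fixture
def reversion_config() -> SimulationConfig:
    """Inducible-efficiency scenario that reverts to wild type.

    e_W = 0.8, f = 0.7 switched to e_W' = 0.1 in 90% of individuals from
    generation 10 on.
    """
    return SimulationConfig(
        params=DriveParams(e_W=0.8, f=0.7, e_W_induced=0.1),
        variant=ModelVariant.INDUCIBLE_EFFICIENCY,
        induction=InductionSettings(alpha=0.9, start_generation=10, enabled=True),
    )


@pytest.fixture
def persistence_config() -> SimulationConfig:
    """Inducible-efficiency scenario the signal cannot revert.

    e_W = 1, f = 0.95 switched to e_W' = 0.2 in 90% of individuals; the
    drive still fixes, only slower.
    """
    return SimulationConfig(
        params=DriveParams(e_W=1.0, f=0.95, e_W_induced=0.2),
        variant=ModelVariant.INDUCIBLE_EFFICIENCY,
        induction=InductionSettings(alpha=0.9, start_generation=10, enabled=True),
    )
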