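import pytest

from matbsim import NullOperator, SimulationConfig, run


@pytest.fixture
def base_config() -> SimulationConfig:
    """Small, fully-defaulted session config."""
    return SimulationConfig(duration=120.0, master_seed=7)


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Config with no discrete events, no drift, no drains: a static world."""
    return SimulationConfig.model_validate({
        "duration": 60.0,
        "master_seed": 1,
        "demand": {"event_counts": {"sysmon": 0, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}},
        "tracking": {"speed_level": 0},
        "resman": {"drain_rate": 0.0},
    })


@pytest.fixture(scope="session")
def null_session_300():
    """One 300 s default-demand session with the null operator, shared
    across tests that only read the log."""
    config = SimulationConfig(duration=300.0, master_seed=11)
    return config, run(config, NullOperator())
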