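import pytest

from whiskadapt import SessionConfig, generate_session


@pytest.fixture(scope="session")
def noiseless_shared_session():
    """Noiseless two-whisker session with adaptation shared across whiskers."""
    cfg = SessionConfig(
        seed=3, n_trials=80, p_go=1.0, noise="none", baseline_rate_hz=0.0,
        whisker_specific=False,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def noiseless_specific_session():
    """Noiseless session where adaptation tracks per-whisker touch count."""
    cfg = SessionConfig(
        seed=3, n_trials=80, p_go=1.0, noise="none", baseline_rate_hz=0.0,
        whisker_specific=True,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def poisson_session():
    """Realistic session with Poisson spiking and background activity."""
    cfg = SessionConfig(seed=5, n_trials=90, p_go=0.7)
    return generate_session(cfg)
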