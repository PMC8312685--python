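import pytest
from hypothesis import HealthCheck, settings

import trisyn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: thermal voltage recomputed independently of the package (V)
VT = 8.3145 * 310.0 / 96480.0


@pytest.fixture(scope="session")
def default_config():
    return trisyn.default_config()


@pytest.fixture(scope="session")
def prepared(default_config):
    """Calibrated default model (GAT-3 on, GABA_A on both neurons)."""
    return trisyn.prepare(default_config)


@pytest.fixture(scope="session")
def quiet_run():
    """5 s unstimulated run of the default model."""
    cfg = trisyn.default_config(duration=5.0)
    proto = trisyn.Protocol(amplitude=0.0, window_start=1e9,
                            window_duration=0.0, total_duration=5.0)
    return trisyn.run(cfg, proto)


@pytest.fixture(scope="session")
def driven_run():
    """Short stimulated GAT-3-on run that completes without leaving the
    physical domain (2 s stimulus inside 7 s)."""
    cfg = trisyn.default_config(duration=7.0)
    proto = trisyn.Protocol(window_start=5.0, window_duration=2.0,
                            total_duration=7.0)
    return cfg, proto, trisyn.run(cfg, proto)
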