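import pytest

import trisyn


@pytest.fixture(scope="session")
def control_result():
    """One control simulation shared by read-only tests (12 s, seed 1)."""
    cfg = trisyn.build_default_network(seed=1, duration=12000.0)
    return cfg, trisyn.integrate_network(cfg)


@pytest.fixture(scope="session")
def henon_series():
    from trisyn.benchmarks import henon_map

    return henon_map(n=10000, seed=0)


@pytest.fixture(scope="session")
def lorenz_x():
    from trisyn.benchmarks import lorenz_series

    return lorenz_series(n=10000)


@pytest.fixture(scope="session")
def noisy_sine_series():
    from trisyn.benchmarks import noisy_sine

    return noisy_sine(period=100.0, n=20000, noise=0.1, seed=0)
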