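import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_phantom():
    """64^3 phantom with moderate deformation, shared by registration tests."""
    from liverquant.synthetic import PhantomSpec, make_phantom
    spec = PhantomSpec(grid_shape=(64, 64, 64), liver_center=(32, 32, 32),
                       liver_axes=(24.0, 21.0, 19.0), lesion_center=(36.0, 33.0, 32.0),
                       lesion_radius=12.0, max_magnitude=5.0, seed=7)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def bench_moderate():
    """Full-pipeline benchmark, 5 phantoms, 6 mm peak deformation."""
    from liverquant.experiments import registration_benchmark
    return registration_benchmark(range(5), max_magnitude=6.0)


@pytest.fixture(scope="session")
def bench_large():
    """Full-pipeline benchmark, 5 phantoms, 10 mm peak deformation."""
    from liverquant.experiments import registration_benchmark
    return registration_benchmark(range(5), max_magnitude=10.0)
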