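import pytest
from hypothesis import HealthCheck, settings

import sparsespike as sp

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_spec():
    """A small balanced random network shared by routing tests."""
    params = sp.BenchmarkParams(N=60, K=6)
    spec = sp.generate_benchmark(params, seed=7)
    spec.validate()
    return spec
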