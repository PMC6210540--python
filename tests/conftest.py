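import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_suite():
    """Reduced-size benchmark suite shared by tests that only need
    amplitude statistics, not full-size frames."""
    from blcodec.phantom import make_benchmark_suite

    return make_benchmark_suite(seed=0, rows=512, cols=64)
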