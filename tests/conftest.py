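import numpy as np
import pytest
from hypothesis import settings

import rwcontour as rw

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("suite")

#: Reduced phantom used throughout the unit tests; the acceptance tests run
#: the full-size default phantom.
SMALL_SHAPE = (44, 192, 192)


@pytest.fixture(scope="session")
def small_phantom() -> rw.PhantomOutput:
    return rw.generate(rw.PhantomSpec(shape=SMALL_SHAPE, rng_seed=1))


@pytest.fixture(scope="session")
def small_run(small_phantom) -> rw.RunResult:
    return rw.run(small_phantom.volume, small_phantom.seeds,
                  small_phantom.config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
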