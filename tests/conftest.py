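import numpy as np
import pytest

import fieldlab as fl


@pytest.fixture
def config():
    return fl.AnalysisConfig()


@pytest.fixture
def air_quiet():
    """Air-condition parameters with measurement noise switched off."""
    return fl.preset("air", noise_sd=0.0, seed=11)


@pytest.fixture
def single_response(air_quiet):
    """One noise-free sweep with a single suprathreshold stimulus at 20 ms."""
    return fl.simulate_sweep(air_quiet, 100.0, [20.0])


def make_sweep(samples, dt=0.1, **kw):
    return fl.Sweep(samples=np.asarray(samples, dtype=float),
                    sample_interval=dt, **kw)


@pytest.fixture
def make_sweep_fn():
    return make_sweep
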