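import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default two-section phantom without noise, motion or gas artifact."""
    from strictureqmri import PhantomSpec, make_phantom

    spec = PhantomSpec(snr=np.inf, gas_rim_fraction=0.0, seed=7)
    echo, dwi, truth = make_phantom(spec)
    return spec, echo, dwi, truth


@pytest.fixture(scope="session")
def gas_phantom():
    """Noiseless phantom with a gas-transition rim on 40% of the inner wall."""
    from strictureqmri import PhantomSpec, make_phantom

    spec = PhantomSpec(snr=np.inf, gas_rim_fraction=0.4, gas_t2star=3.0,
                       seed=11)
    echo, dwi, truth = make_phantom(spec)
    return spec, echo, dwi, truth
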