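import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from iphquant.phantom import PhantomConfig, IPHSpec, NoiseSpec


@pytest.fixture
def noiseless_config():
    """High-contrast subject with no noise and no muscle variability."""
    cfg = PhantomConfig(noise=NoiseSpec(model="rician", sigma=0.0),
                        iph=IPHSpec(intensity_ratio=2.5), seed=7)
    cfg.muscle.sd = 0.0
    return cfg


@pytest.fixture
def noisy_config():
    return PhantomConfig(iph=IPHSpec(intensity_ratio=2.5), seed=7)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * (a & b).sum() / s
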