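import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trabecular_patch():
    """A deterministic 10x30 trabecular ROI patch (no implant)."""
    from perifract.synth import TrabecularPhantomParams, make_phantom

    img = make_phantom(
        TrabecularPhantomParams(width=96, height=96, hurst=0.4, seed=7,
                                mean_gray=120, contrast=25, noise_sd=2)
    )
    return img.pixels[20:50, 30:40].copy()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A deterministic noiseless phantom for registration tests."""
    from perifract.synth import TrabecularPhantomParams

    return TrabecularPhantomParams(
        width=128, height=128, hurst=0.5, seed=3, noise_sd=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
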