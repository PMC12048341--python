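import numpy as np
import pytest

from opmr import nir_sim, pipeline


def low_noise_params(N: int = 10) -> nir_sim.RenderParams:
    """Rendering conditions with geometry jitter but negligible noise/blur."""
    return nir_sim.RenderParams(
        pitch=nir_sim.default_pitch(N),
        background_noise_sigma=0.002,
        blur_sigma_range=(0.0, 0.0),
        motion_blur_len_range=(0.0, 0.0),
        gain_range=(1.0, 1.0),
        exposure_range=(1.0, 1.0),
    )


@pytest.fixture(scope="session")
def cfg10():
    return pipeline.CodecConfig(N=10)


@pytest.fixture(scope="session")
def cfg17():
    return pipeline.CodecConfig(N=17)


@pytest.fixture(scope="session")
def cfg10_low_noise():
    return pipeline.CodecConfig(N=10, render_params=low_noise_params(10))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
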