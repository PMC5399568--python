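import numpy as np
import pytest

from lobequant.detection import DetectionParams
from lobequant.shells import ShellParams
from lobequant.synthesis import SynthesisParams, generate_lobe_image


@pytest.fixture(scope="session")
def small_params() -> SynthesisParams:
    """A fast, small lobe: 16 nuclei on a 192x192 frame, noise-free."""
    return SynthesisParams(
        image_height=192,
        image_width=192,
        n_nuclei=16,
        noise_sd=0.0,
        positive_fraction=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_lobe(small_params):
    return generate_lobe_image(small_params, lobe_id="small", group_label="g")


@pytest.fixture(scope="session")
def noisy_lobe():
    """Default study conditions (512x512, 100 nuclei, peak SNR ~ 5)."""
    params = SynthesisParams(seed=7)
    return generate_lobe_image(params, lobe_id="noisy", group_label="g")


@pytest.fixture
def det_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def shell_params() -> ShellParams:
    return ShellParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
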