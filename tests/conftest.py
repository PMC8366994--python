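import numpy as np
import pytest

from globquant import SlideImage, SlideSpec, generate_slide


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def pasd_slide():
    """A rendered PAS-D slide with ground truth, shared across tests."""
    spec = SlideSpec(
        seed=7, n_globules=25, tissue_area_mm2=0.2, canvas_px=(1000, 1000)
    )
    image, truth = generate_slide(spec)
    slide = SlideImage(name="pasd_fixture", levels=[image], mpp=spec.mpp)
    return slide, truth, spec


def make_slide(arr: np.ndarray, mpp: float = 0.5, name: str = "mem") -> SlideImage:
    return SlideImage(name=name, levels=[arr], mpp=mpp)
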