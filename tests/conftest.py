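import numpy as np
import pytest
from hypothesis import settings

from faceiq.imaging import FaceCropBox, GreyImage
from faceiq.synthetic_fixtures import ImageSpec, make_image

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ramp_image() -> GreyImage:
    """4x4 raster with values 0..15, row-major."""
    return GreyImage(np.arange(16).reshape(4, 4))


@pytest.fixture
def small_face_image():
    """Synthetic 120x90 image with a 40x30 face box and known exposure."""
    spec = ImageSpec(
        width=120, height=90, box=FaceCropBox(30, 20, 40, 30),
        ufr=0.25, ofr=0.10, seed=7,
    )
    return make_image(spec) + (spec,)


@pytest.fixture
def fixture_folder(tmp_path):
    """Folder of three tiny PNGs with hand-known histograms."""
    rasters = {
        "a_const.png": np.zeros((2, 2), dtype=np.uint8),
        "b_spread.png": np.array([[0, 5], [128, 250]], dtype=np.uint8),
        "c_white.png": np.full((3, 3), 255, dtype=np.uint8),
    }
    for name, arr in rasters.items():
        GreyImage(arr).save(tmp_path / name)
    return tmp_path, rasters
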