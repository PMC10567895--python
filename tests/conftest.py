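import pytest
from PIL import Image

from facefd import AnatomicalPriors, CameraSpec, dslr_camera_specs, smartphone_camera_specs


@pytest.fixture
def simple_cam() -> CameraSpec:
    """Idealised camera with round numbers: f = 100 mm, 5 um pixels."""
    return CameraSpec("ideal", focal_length_mm=100.0, pixel_size_mm=0.005)


@pytest.fixture
def full_frame_cam() -> CameraSpec:
    """Full-frame body (6.55 um pitch) with a 100 mm prime."""
    return CameraSpec("ff_100", focal_length_mm=100.0, pixel_size_mm=0.00655)


@pytest.fixture
def priors30() -> AnatomicalPriors:
    return AnatomicalPriors(mean_pfl_mm=30.0, sd_pfl_mm=1.2)


@pytest.fixture(scope="session")
def all_fixture_cameras() -> dict:
    return {**dslr_camera_specs(), **smartphone_camera_specs()}


@pytest.fixture
def jpeg_factory(tmp_path):
    """Write a small JPEG, optionally with an EXIF FocalLength tag, return its path."""

    def make(name: str, focal_length=None):
        path = tmp_path / name
        im = Image.new("RGB", (8, 8), "gray")
        if focal_length is None:
            im.save(path)
        else:
            exif = Image.Exif()
            exif[0x920A] = focal_length
            im.save(path, exif=exif)
        return path

    return make
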