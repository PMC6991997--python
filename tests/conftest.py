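import numpy as np
import pytest

from odseg.synth import SceneSpec, generate_fundus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def easy_scene():
    """One rendered easy scene (vessels, one lesion, no haze) + ground truth."""
    spec = SceneSpec(seed=42, lesion_count=1)
    image, gt = generate_fundus(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def vessel_crop(easy_scene):
    """300 px crop around the true OD center, with cropped ground truth."""
    spec, image, gt = easy_scene
    r0 = int(round(spec.od_center[0])) - 150
    c0 = int(round(spec.od_center[1])) - 150
    sl = (slice(r0, r0 + 300), slice(c0, c0 + 300))
    return image[sl], gt.od_mask[sl], gt.vessel_mask[sl], gt.vessel_centerline[sl]
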