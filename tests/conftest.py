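import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vbmorph import PhantomConfig, SegmentationMask, generate_vb_phantom
from vbmorph.centerline import identify_vessel_tree, skeletonize
from vbmorph.segmentation import largest_components, threshold_segment
from vbmorph.synthetic import make_parametric_centerline, sweep_tubes

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

SPACING = 0.5


@pytest.fixture(scope="session")
def bent_phantom():
    """Default Y phantom: VA diameters 3.4/2.8 mm (left dominant), BA bowed
    3 mm to the right."""
    cfg = PhantomConfig(ba_bend_mm=3.0, ba_bend_side="right")
    vol, gt = generate_vb_phantom(cfg, seed=1, spacing=SPACING)
    return vol, gt


@pytest.fixture(scope="session")
def bent_mask(bent_phantom):
    vol, _ = bent_phantom
    return largest_components(threshold_segment(vol), k=1)


@pytest.fixture(scope="session")
def bent_tree(bent_mask):
    return identify_vessel_tree(skeletonize(bent_mask))


@pytest.fixture(scope="session")
def cylinder():
    """Straight tube r=2 mm, L=40 mm along +z at 0.5 mm spacing."""
    axis = make_parametric_centerline("straight", start=(0, 0, 0), end=(0, 0, 40))
    vol = sweep_tubes({"tube": axis}, {"tube": 2.0}, SPACING, seed=0)
    return vol, axis


@pytest.fixture(scope="session")
def cylinder_mask(cylinder):
    vol, _ = cylinder
    return threshold_segment(vol)


@pytest.fixture(scope="session")
def sphere_mask():
    """Digitized sphere r=8 mm at 0.5 mm spacing."""
    x, y, z = np.indices((41, 41, 41)) * SPACING
    c = 10.0
    ball = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 8.0 ** 2
    return SegmentationMask(ball, (SPACING,) * 3)
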