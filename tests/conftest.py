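import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tracermap.atlas_volume import AtlasVolume
from tracermap.synthetic_fixtures import (
    CALIBRATION_PROFILE,
    PhantomVolumeSpec,
    Region,
    default_scene,
    make_fiber_image,
    make_phantom_volume,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibration_profile():
    return CALIBRATION_PROFILE


@pytest.fixture(scope="session")
def scene_and_image():
    scene = default_scene(seed=7)
    rgb, truth = make_fiber_image(scene)
    return scene, rgb, truth


@pytest.fixture(scope="session")
def linear_phantom() -> AtlasVolume:
    """Phantom with a linear template field (exact trilinear oracle)."""
    return make_phantom_volume(PhantomVolumeSpec(dims=(20, 22, 24)))


@pytest.fixture(scope="session")
def labeled_phantom() -> AtlasVolume:
    """Phantom with two labeled regions and a mm-scale affine."""
    affine = np.diag([0.1, 0.1, 0.1, 1.0])
    affine[:3, 3] = (-1.6, -1.6, -1.6)
    spec = PhantomVolumeSpec(
        dims=(32, 32, 32),
        affine=affine,
        regions=[
            Region(7, "phantom nucleus A", "ellipsoid", (10.0, 16.0, 16.0), (5.0, 6.0, 5.0)),
            Region(12, "phantom nucleus B", "box", (24.0, 16.0, 16.0), (4.0, 8.0, 8.0)),
        ],
        template_field=("blobs", 3),
    )
    return make_phantom_volume(spec)
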