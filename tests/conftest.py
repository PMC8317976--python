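import numpy as np
import pytest
from hypothesis import settings

from carmplan.frustum import Frustum, Intrinsics, project_point
from carmplan.simulate import TubePhantom, default_pelvis, orbit_frustums
from carmplan.tool_planning import TargetLine2D

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_view_frustums():
    """Two orbit views 90 degrees apart about the origin isocenter."""
    return orbit_frustums([0.0, 0.0, 0.0], [0.0, 90.0])


@pytest.fixture
def tube():
    """Oblique tube phantom crossing the isocenter region."""
    return TubePhantom(entry=[5.0, -8.0, -40.0], exit=[-3.0, 6.0, 42.0])


@pytest.fixture
def pelvis():
    return default_pelvis()


@pytest.fixture
def wire_targets(two_view_frustums, tube):
    """Noiseless projected tube-centerline targets in both views."""
    out = []
    for fr in two_view_frustums:
        e = project_point(fr, tube.entry)
        x = project_point(fr, tube.exit)
        out.append(TargetLine2D(fr.frustum_id, e, x))
    return out


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


def random_transform(rng, trans_scale=100.0):
    from carmplan.geometry import RigidTransform

    return RigidTransform(random_rotation(rng), rng.uniform(-trans_scale, trans_scale, 3))
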