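import numpy as np
import pytest

from rbmicv import phantom as ph
from rbmicv.core_image import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel=1.0, trans=(0.0, 0.0, 0.0), space="native"):
    affine = np.eye(4)
    affine[:3, :3] *= voxel
    affine[:3, 3] = trans
    return Volume3D(voxels=np.asarray(data), affine=affine, space_tag=space)


@pytest.fixture
def small_spec():
    """Half-size phantom (48³) for fast end-to-end tests."""
    return ph.PhantomSpec(field_mode="3T").scaled(0.5)


@pytest.fixture(scope="session")
def default_template():
    """Template assets for the default 3T spec (shared, read-only)."""
    return ph.make_template(ph.PhantomSpec(field_mode="3T"))
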