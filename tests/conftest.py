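import numpy as np
import pytest

from inhaledose.materials import material
from inhaledose.nuclides import load_builtin_library
from inhaledose.phantom import VoxelPhantom, build_reference_phantom
from inhaledose.registration import SourceEnsemble


@pytest.fixture(scope="session")
def library():
    return load_builtin_library()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_phantom():
    return build_reference_phantom(1.0)


def make_box_phantom(mat_name="water", n=31, h=1.0, layers=None):
    """Uniform (or z-layered) cube phantom for transport benchmarks.

    ``layers`` maps z-index ranges to material names: [(z0, z1, name), ...];
    remaining voxels take ``mat_name``.
    """
    ids = np.zeros((n, n, n), dtype=np.uint16)
    names = {0: mat_name}
    mats = {0: material(mat_name)}
    if layers:
        for k, (z0, z1, name) in enumerate(layers, start=1):
            ids[:, :, z0:z1] = k
            names[k] = name
            mats[k] = material(name)
    origin = np.array([-n * h / 2.0] * 3)
    return VoxelPhantom(ids, h, origin, names, mats)


def center_source(phantom, nuclide=None):
    c = np.array(phantom.shape) // 2
    idx = c[None, :]
    return SourceEnsemble(idx, phantom.voxel_center(idx), np.array([1.0]), nuclide)


@pytest.fixture
def water_phantom():
    return make_box_phantom("water", n=31, h=1.0)
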