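import numpy as np
import pytest

from elopath import (PhantomSpec, compute_fiber_scores, compute_gm_scores,
                     make_phantom)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 scene: fast enough for per-test use, rich enough to be non-trivial."""
    return make_phantom(PhantomSpec(grid_shape=(32, 32, 32), seed=7))


@pytest.fixture(scope="session")
def small_scene(small_phantom):
    """Phantom plus its score tables."""
    ph = small_phantom
    gm = compute_gm_scores(ph.fc, ph.sc, ph.parcellation)
    fib = compute_fiber_scores(ph.tractogram, ph.parcellation, gm)
    return ph, gm, fib


@pytest.fixture(scope="session")
def full_phantom():
    """Default-size (64^3, 2 mm) scene used by the heavier geometry checks."""
    return make_phantom(PhantomSpec(seed=11))


@pytest.fixture
def block_parcellation():
    """Two 4x4x4 labeled blocks in a 12^3 grid of 2 mm voxels.

    Label 1 occupies voxel indices [1,4]^3; label 2 occupies [7,10] in x,
    [1,4] in y,z. Identity-scaled affine (2 mm, origin at voxel 0 center).
    """
    from elopath import Parcellation

    vol = np.zeros((12, 12, 12), dtype=np.int32)
    vol[1:5, 1:5, 1:5] = 1
    vol[7:11, 1:5, 1:5] = 2
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return Parcellation(label_volume=vol, affine=affine)
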