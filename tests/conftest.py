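import numpy as np
import pytest

from centiloid.synthetic import PhantomSpec, generate_phantom
from centiloid.volume_io import VoiMask, VolumeGrid


@pytest.fixture
def eye_affine():
    return np.diag([2.0, 2.0, 2.0, 1.0])


@pytest.fixture
def small_volume(eye_affine):
    """4x4x4 deterministic volume with distinct values per voxel."""
    vals = np.arange(64, dtype=float).reshape(4, 4, 4)
    return VolumeGrid(values=vals, affine=eye_affine)


@pytest.fixture
def full_mask(eye_affine):
    return VoiMask(weights=np.ones((4, 4, 4)), affine=eye_affine, name="all")


@pytest.fixture
def phantom():
    """Noise-free two-level phantom: cortex 2.0, cerebellum 1.25, SUVR 1.6."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))
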