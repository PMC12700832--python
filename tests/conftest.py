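import numpy as np
import pytest

from nanoquant.phantom import PhantomConfig, generate_phantom
from nanoquant.volume_io import LabelVolume, VoxelGrid


@pytest.fixture(scope="session")
def small_phantom():
    """A small default-condition phantom shared across read-only tests."""
    return generate_phantom(PhantomConfig(shape=(32, 64, 64), particles_per_organ=6), seed=42)


@pytest.fixture()
def toy_volume():
    """A 4x4x4 volume with two organs and a hand-checkable mask."""
    data = np.full((4, 4, 4), 10.0, dtype=np.float32)
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[:, :2, :] = 1
    labels[:, 2:, :] = 2
    mask = np.zeros((4, 4, 4), dtype=np.uint8)
    data[0, 0, 0] = 30.0
    data[0, 0, 1] = 20.0
    mask[0, 0, 0] = 1
    mask[0, 0, 1] = 1
    organs = LabelVolume(labels, {1: "liver", 2: "spleen"})
    return VoxelGrid(data), organs, mask
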