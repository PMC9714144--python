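import numpy as np
import pytest

from flow4d.data_model import PhaseMask4D, VelocityField4D
from flow4d.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def uniform_phantom():
    return make_phantom(PhantomSpec(kind="uniform", uniform_speed_cms=10.0))


@pytest.fixture(scope="session")
def rotation_phantom():
    # two frames at half-cycle spacing: steady field, no dt clamping for
    # coarse convergence steps
    return make_phantom(PhantomSpec(kind="rotation", n_frames=2,
                                    frame_interval_ms=500.0))


@pytest.fixture(scope="session")
def small_two_channel():
    # L=10 channel, a=6, b=7 -> plug fractions (30, 30, 40, 0), halved with
    # the static channel to (15, 15, 20, 50)
    spec = PhantomSpec(kind="two_channel", length_voxels=10,
                       cross_section=(4, 4), margin_voxels=2,
                       n_frames=20, frame_interval_ms=40.0,
                       systole_frames=8, a_voxels=6, b_voxels=7)
    return make_phantom(spec)


def uniform_field(speed_cms=(10.0, 0.0, 0.0), shape=(8, 8, 8), n_frames=10,
                  voxel=2.0, frame_interval=40.0):
    vel = np.zeros((*shape, n_frames, 3))
    vel[..., 0], vel[..., 1], vel[..., 2] = speed_cms
    return VelocityField4D(velocity=vel, voxel_size=np.full(3, voxel),
                           frame_interval=frame_interval)


def block_mask(shape=(10, 10, 10), n_frames=10, voxel=1.0, label=2):
    labels = np.full((*shape, n_frames), label, dtype=np.uint8)
    return PhaseMask4D(labels, np.full(3, voxel), 40.0)
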