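import numpy as np
import pytest

from deepmpm.core_io import AcquisitionMeta, ImageStack, Roi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_stack():
    """2-channel, 4-plane, 16x16 stack with per-plane energies."""
    rng = np.random.default_rng(0)
    px = rng.uniform(0, 100, size=(2, 4, 16, 16))
    return ImageStack(
        pixels=px,
        axis_kind="z",
        pixel_size_um=0.5,
        plane_step=5.0,
        channel_names=["green", "red"],
        meta=AcquisitionMeta(per_plane_energy_nj=np.array([1.0, 2.0, 3.0, 4.0])),
    )


@pytest.fixture
def full_roi():
    def make(shape):
        return Roi(mask=np.ones(shape, dtype=bool), label="full")

    return make
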