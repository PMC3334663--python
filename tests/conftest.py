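import numpy as np
import pytest

import osteoct as o

SPACING = 8.7  # μm, study voxel size


@pytest.fixture(scope="session")
def slab_phantom():
    """Slabs 104.4 μm thick, 261 μm apart: thickness/separation oracle."""
    mask, truth = o.make_slab_phantom(104.4, 261.0, SPACING, (130, 96, 96))
    return mask, truth


@pytest.fixture(scope="session")
def rod_phantom():
    """Rods of radius 43.5 μm on a 261 μm square lattice."""
    mask, truth = o.make_rod_phantom(43.5, 261.0, SPACING, (48, 120, 120))
    return mask, truth


@pytest.fixture(scope="session")
def subchondral_phantom():
    """Plate 104.4 μm with 20% drilled pores over a rod compartment."""
    return o.make_subchondral_phantom(104.4, 20.0, SPACING, (96, 96, 96),
                                      seed=2)


@pytest.fixture
def full_voi():
    def make(shape, spacing=SPACING, compartment="total"):
        return o.VoiMask(np.ones(shape, dtype=bool), compartment, spacing)
    return make


@pytest.fixture
def interior_voi():
    """VOI excluding an in-plane margin, where sphere fitting is border-free."""
    def make(shape, margin, spacing=SPACING, compartment="total"):
        m = np.zeros(shape, dtype=bool)
        m[:, margin:shape[1] - margin, margin:shape[2] - margin] = True
        return o.VoiMask(m, compartment, spacing)
    return make
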