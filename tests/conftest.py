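"""Shared fixtures: small grids, printed-table inputs, seeded studies."""

from __future__ import annotations

import numpy as np
import pytest

from y90quant.imgcore import VoiMask, VoxelGrid

# Published per-patient administered / liver-VOI-estimated activities (MBq)
# used as worked-example inputs for the percent-error accounting.
TABLE2_ROWS = [
    ("Pat_1", 555, 480, 14),
    ("Pat_2", 570, 652, -14),
    ("Pat_3", 759, 967, -27),
    ("Pat_4", 781, 788, -1),
    ("Pat_5", 966, 1251, -30),
    ("Pat_6", 999, 1009, -1),
    ("Pat_7", 1203, 1202, 0),
    ("Pat_8", 1236, 1221, 1),
    ("Pat_9", 1262, 1288, -2),
    ("Pat_10", 1436, 1350, 6),
    ("Pat_11", 1517, 1572, -4),
    ("Pat_12", 2072, 2188, -6),
]

# Measured activities inside the eight phantom spheres (MBq), largest first;
# the stated total is 27 MBq.
TABLE1_SPHERE_ACTIVITIES = {
    34: 11.10, 31: 8.88, 25: 4.44, 16: 1.11, 12: 0.56, 10: 0.28, 8: 0.14, 2: 0.0,
}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid(rng):
    """Random positive 8x8x6 cps grid at the clinical voxel size."""
    return VoxelGrid(rng.uniform(1.0, 10.0, (8, 8, 6)), (4.664,) * 3, units="cps")


@pytest.fixture
def ball_mask():
    """Spherical mask centred in a 16^3 lattice (radius 4 voxels)."""
    idx = np.indices((16, 16, 16))
    dist2 = sum((idx[ax] - 7.5) ** 2 for ax in range(3))
    return VoiMask(dist2 <= 16.0, "sphere")
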