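import numpy as np
import pytest

from wmh3d import zernike


@pytest.fixture(scope="session")
def grid16():
    return zernike.build_unit_ball_grid(16)


@pytest.fixture(scope="session")
def ellipsoid32():
    """A ~300-voxel ellipsoid centred in a 32^3 cube (binary)."""
    side = 32
    c = (side - 1) / 2
    ax = np.arange(side) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return ((x / 5.0) ** 2 + (y / 3.5) ** 2 + (z / 2.5) ** 2 <= 1).astype(float)


def axis_rotations():
    """All 24 proper axis-aligned rotations as (perm, flips) actions."""
    from itertools import permutations, product

    out = []
    for perm in permutations(range(3)):
        for flips in product([1, -1], repeat=3):
            mat = np.zeros((3, 3))
            for i, p in enumerate(perm):
                mat[i, p] = flips[i]
            if np.linalg.det(mat) > 0:
                out.append((perm, flips))
    return out


def rotate_cube(cube, perm, flips):
    out = np.transpose(cube, perm)
    for ax, f in enumerate(flips):
        if f < 0:
            out = np.flip(out, axis=ax)
    return out
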