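from __future__ import annotations

import numpy as np
import pytest

from nodeval import LabelVolume


def binary_volume(arr, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    return LabelVolume(voxels=np.asarray(arr, dtype=np.int16), spacing=spacing, kind="binary")


def cube_mask(shape, lo, size) -> np.ndarray:
    m = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(l, l + s) for l, s in zip(lo, (size,) * 3 if np.isscalar(size) else size))
    m[sl] = 1
    return m


def digital_sphere(diameter_vox: int, spacing=(1.0, 1.0, 1.0), pad: int = 2) -> LabelVolume:
    """Sphere of the given diameter in physical mm (isotropic in mm)."""
    sx, sy, sz = spacing
    r = diameter_vox / 2.0
    nx = int(np.ceil(2 * r / sx)) + 2 * pad + 1
    ny = int(np.ceil(2 * r / sy)) + 2 * pad + 1
    nz = int(np.ceil(2 * r / sz)) + 2 * pad + 1
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    x, y, z = np.mgrid[0:nx, 0:ny, 0:nz]
    d2 = ((x - cx) * sx) ** 2 + ((y - cy) * sy) ** 2 + ((z - cz) * sz) ** 2
    return binary_volume((d2 <= r * r).astype(np.int16), spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_mask(rng, shape=(10, 10, 6), p=0.25) -> np.ndarray:
    return (rng.random(shape) < p).astype(np.int16)
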