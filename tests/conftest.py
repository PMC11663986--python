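import warnings

import numpy as np
import pytest

from cardiodose.contours import StructureMask

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def sphere_mask(radius_mm, spacing=(1.0, 1.0, 1.0), pad_mm=4.0, name="sphere"):
    """Rasterized sphere centred in its own grid (voxel-centre inclusion)."""
    spacing = np.asarray(spacing, dtype=float)
    half = radius_mm + pad_mm
    shape = np.ceil(2 * half / spacing).astype(int) + 1
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    c = [(n * s) / 2 for n, s in zip(shape, spacing)]
    vox = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius_mm**2
    return StructureMask(vox, tuple(spacing), name)


def random_blob(rng, shape=(16, 16, 12), spacing=(2.0, 2.0, 3.0), p_seed=0.02):
    """Random connected-ish blob: dilate a sparse seed a few steps."""
    from scipy import ndimage

    vox = rng.random(shape) < p_seed
    vox[tuple(rng.integers(2, np.array(shape) - 2))] = True  # never empty
    vox = ndimage.binary_dilation(vox, iterations=rng.integers(1, 3))
    return StructureMask(vox, spacing, "blob")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
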