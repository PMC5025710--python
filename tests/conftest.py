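import numpy as np
import pytest

from cyclomap.map_core import AtomicModel, Image2D, VoxelGrid
from cyclomap.synthetic_data import _SUBUNIT_BLOBS


@pytest.fixture(scope="session")
def blob_model():
    """Small rigid pseudo-atomic model (the phantom subunit cluster)."""
    return AtomicModel(
        elements=np.array(["C"] * len(_SUBUNIT_BLOBS)),
        weights=_SUBUNIT_BLOBS[:, 3] * 100.0,
        coords=_SUBUNIT_BLOBS[:, :3] * 20.0,
    )


@pytest.fixture(scope="session")
def smooth_symmetric_phantom():
    """Analytically axially symmetric 3D phantom + its exact side view.

    Gaussian ring with z-varying radius plus a central core; smooth enough
    that band-limit effects are negligible.
    """
    n = 96
    c = n // 2
    z = (np.arange(n) - c)[:, None, None]
    y = (np.arange(n) - c)[None, :, None]
    x = (np.arange(n) - c)[None, None, :]
    r = np.hypot(y, x)
    ring_radius = 10 + 3 * np.sin(2 * np.pi * z / 64) * np.exp(-(z ** 2) / (2 * 14.0 ** 2))
    data = (np.exp(-((r - ring_radius) ** 2) / (2 * 5.0 ** 2))
            * np.exp(-(z ** 2) / (2 * 12.0 ** 2))
            + 0.7 * np.exp(-(r ** 2 + 0.5 * z ** 2) / (2 * 6.0 ** 2)))
    grid = VoxelGrid(data, 2.0)
    side = Image2D(data.sum(axis=1), 2.0)
    return grid, side


@pytest.fixture(scope="session")
def noise_signal_grid():
    """Random smooth signal with power in every Fourier shell (for FSC)."""
    from scipy import ndimage
    rng = np.random.default_rng(42)
    data = ndimage.gaussian_filter(rng.standard_normal((64, 64, 64)), 1.5)
    return VoxelGrid(data, 2.0)


TINY_PDB = """\
ATOM      1  N   ALA A   1      10.000  12.000   8.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.200  12.500   8.600  1.00  0.00           C
ATOM      3  C   ALA A   1      12.100  11.400   9.100  1.00  0.00           C
ATOM      4  O   ALA A   1      11.900  10.200   8.900  1.00  0.00           O
ATOM      5  H   ALA A   1      10.100  12.900   7.500  1.00  0.00           H
ATOM      6  N   GLY A   2      13.200  11.800   9.800  1.00  0.00           N
ATOM      7  CA  GLY A   2      14.200  10.900  10.400  1.00  0.00           C
ATOM      8  C   GLY A   2      15.400  11.600  11.000  1.00  0.00           C
ATOM      9  SE  MSE A   3      16.000  13.000  12.000  1.00  0.00          SE
ATOM     10  N   ALA B 219      -5.000  -6.000  -7.000  1.00  0.00           N
ATOM     11  CA  ALA B 219      -4.000  -5.200  -6.300  1.00  0.00           C
ATOM     12  N   ALA B 220      -3.000  -4.000  -5.000  1.00  0.00           N
ATOM     13  CA  ALA B 221      -2.000  -3.000  -4.000  1.00  0.00           C
END
"""


@pytest.fixture()
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path
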