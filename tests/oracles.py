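"""Independent reference implementations used only to cross-check the
package; none of these share code with the implementation under test."""

import numpy as np
from scipy.linalg import solve_triangular


def onion_peel_matrix(nr: int) -> np.ndarray:
    """Forward line-projection matrix of concentric annuli.

    ``W[i, j]`` is the chord length of the annulus ``[j-1/2, j+1/2]``
    (``j = 0`` is the central disk) at lateral offset ``x = i``; the matrix
    is upper triangular, so inverting the Abel projection reduces to a
    back-substitution ("onion peeling").
    """
    W = np.zeros((nr, nr))
    for i in range(nr):
        x = float(i)
        for j in range(i, nr):
            r_out, r_in = j + 0.5, max(j - 0.5, 0.0)
            chord_out = np.sqrt(max(r_out ** 2 - x ** 2, 0.0))
            chord_in = np.sqrt(max(r_in ** 2 - x ** 2, 0.0))
            W[i, j] = 2.0 * (chord_out - chord_in)
    return W


def inverse_abel_slices(side: np.ndarray) -> np.ndarray:
    """Per-z-slice inverse Abel transform of a (symmetrized) side view.

    ``side`` is (nz, nx) with the rotation axis at column ``nx // 2``.
    Returns (nz, nr) radial profiles with ``nr = nx // 2 - 1``.
    """
    nz, nx = side.shape
    c = nx // 2
    nr = c - 1
    idx = np.arange(nr)
    half = 0.5 * (side[:, c + idx] + side[:, c - idx])
    return solve_triangular(onion_peel_matrix(nr), half.T, lower=False).T


def direct_ncc_at_shift(map_data: np.ndarray, probe_data: np.ndarray,
                        shift_voxels) -> float:
    """Direct-space NCC of a map vs a circularly shifted probe."""
    shifted = np.roll(probe_data, shift_voxels,
                      axis=tuple(range(probe_data.ndim)))
    a = map_data - map_data.mean()
    b = shifted - shifted.mean()
    return float((a * b).sum() / (np.linalg.norm(a) * np.linalg.norm(b)))


def splat_2d(coords_xyz: np.ndarray, weights: np.ndarray, rotation: np.ndarray,
             pixel_size: float, box: int, sigma: float) -> np.ndarray:
    """Direct 2D Gaussian splatting of rotated atoms (projection oracle).

    Rotates the atoms, drops z, and accumulates normalized 2D Gaussians of
    width ``sigma`` (Angstrom) weighted per atom; image rows are y.
    """
    rotated = coords_xyz @ rotation.T
    c = box // 2
    yy, xx = np.indices((box, box))
    image = np.zeros((box, box))
    s = sigma / pixel_size
    for (x, y, _), w in zip(rotated, weights):
        py = y / pixel_size + c
        px = x / pixel_size + c
        g = np.exp(-0.5 * (((yy - py) ** 2 + (xx - px) ** 2) / s ** 2))
        image += w * g / (2.0 * np.pi * s ** 2)
    return image


def shell_power_beyond(data: np.ndarray, spacing: float,
                       cutoff: float) -> float:
    """Total spectral power at frequencies beyond ``1/cutoff`` (oracle for
    low-pass attenuation, by direct spectral integration)."""
    F = np.fft.fftn(data)
    freqs = [np.fft.fftfreq(n, d=spacing) for n in data.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    radius = np.sqrt(sum(g * g for g in grids))
    return float((np.abs(F[radius > 1.0 / cutoff]) ** 2).sum())
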