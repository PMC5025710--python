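"""Atomic models to simulated density, volume projection, projection matching.

Atoms are rendered as isotropic Gaussians with a width set by the target
resolution (``sigma = resolution / (pi * sqrt(2))``, i.e. the Gaussian
amplitude falls to one half at spatial frequency ``1/resolution``) and an
integral proportional to the atomic weight.  Projection is
rotate-then-sum with tri-linear resampling; orientations are zyz Euler
angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .map_core import AtomicModel, Image2D, VoxelGrid

__all__ = [
    "sigma_for_resolution",
    "model_to_density",
    "project",
    "side_project",
    "rotation_matrix",
    "orientation_grid",
    "match_projections",
    "MatchResult",
]

#: Gaussian width per resolution; amplitude = 1/2 at frequency 1/resolution.
SIGMA_CONSTANT = 1.0 / (math.pi * math.sqrt(2.0))


def sigma_for_resolution(resolution: float) -> float:
    """Real-space Gaussian sigma (Angstrom) for a nominal resolution."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return resolution * SIGMA_CONSTANT


def rotation_matrix(euler_zyz_deg) -> np.ndarray:
    """3x3 matrix for intrinsic zyz Euler angles in degrees (acts on xyz)."""
    return Rotation.from_euler("ZYZ", euler_zyz_deg, degrees=True).as_matrix()


def model_to_density(model: AtomicModel, voxel_size: float, resolution: float,
                     box: int, strict_bounds: bool = True) -> VoxelGrid:
    """Render an atomic model as a Gaussian-atom density map.

    Coordinates are interpreted relative to the box center voxel
    ``box // 2``.  Each atom contributes a Gaussian normalized so that its
    voxel sum equals its atomic weight; the integrated density of the map
    therefore equals the total model weight.

    Raises
    ------
    ValueError
        If ``strict_bounds`` and any atom (plus a margin of one resolution
        length) falls outside the box; offending atom indices are listed.
        With ``strict_bounds=False`` kernels are clipped at the box edges.
    """
    sigma = sigma_for_resolution(resolution) / voxel_size  # in voxels
    c = box // 2
    # positions in voxel units, array index order (z, y, x)
    pos = model.coords[:, ::-1] / voxel_size + c
    if strict_bounds:
        margin = resolution / voxel_size
        bad = np.where(np.any((pos < margin - 0.5)
                              | (pos > box - 1 - margin + 0.5), axis=1))[0]
        if len(bad):
            raise ValueError(
                f"{len(bad)} atoms outside the box (margin {resolution} A): "
                f"indices {bad[:10].tolist()}{'...' if len(bad) > 10 else ''}")

    data = np.zeros((box, box, box))
    half = max(int(math.ceil(4.0 * sigma)), 1)
    win = np.arange(-half, half + 1)
    for p, w in zip(pos, model.weights):
        i0 = np.round(p).astype(int)
        axes_1d = []
        slices = []
        for ax in range(3):
            g = np.exp(-0.5 * ((win + i0[ax] - p[ax]) / sigma) ** 2)
            lo, hi = i0[ax] - half, i0[ax] + half + 1
            klo = max(0, -lo)
            khi = len(win) - max(0, hi - box)
            if klo >= khi:
                axes_1d = None
                break
            axes_1d.append(g[klo:khi])
            slices.append(slice(max(lo, 0), min(hi, box)))
        if axes_1d is None:
            continue  # atom entirely outside (clipped rendering)
        kernel = (axes_1d[0][:, None, None] * axes_1d[1][None, :, None]
                  * axes_1d[2][None, None, :])
        ksum = kernel.sum()
        if ksum <= 0:
            continue
        data[tuple(slices)] += kernel * (w / ksum)
    return VoxelGrid(data, voxel_size,
                     meta={"render": {"resolution_A": resolution,
                                      "sigma_A": sigma * voxel_size,
                                      "sigma_constant": SIGMA_CONSTANT}})


def _rotated_volume(grid: VoxelGrid, euler_zyz_deg, order: int = 1) -> np.ndarray:
    """Resample ``grid`` rotated by the given zyz Euler angles about box center."""
    grid.require_cubic()
    R = rotation_matrix(euler_zyz_deg)
    # index space is (z, y, x): conjugate by the axis-order flip
    P = np.eye(3)[::-1]
    A = P @ R @ P
    n = grid.data.shape[0]
    c = n // 2
    center = np.full(3, c, dtype=float)
    Ainv = A.T  # rotation: inverse = transpose
    offset = center - Ainv @ center
    return ndimage.affine_transform(grid.data, Ainv, offset=offset,
                                    order=order, mode="constant", cval=0.0)


def project(grid: VoxelGrid, euler_zyz_deg=(0.0, 0.0, 0.0),
            order: int = 1) -> Image2D:
    """Project a cubic grid along the viewing (z) axis after rotation.

    The identity orientation sums the unmodified grid over z.  The pixel
    sum equals the voxel sum up to interpolation losses.
    """
    if tuple(euler_zyz_deg) == (0.0, 0.0, 0.0):
        rotated = grid.require_cubic().data
    else:
        rotated = _rotated_volume(grid, euler_zyz_deg, order=order)
    return Image2D(rotated.sum(axis=0), grid.voxel_size,
                   meta={"orientation_zyz_deg": tuple(euler_zyz_deg)})


def side_project(grid: VoxelGrid) -> Image2D:
    """Exact side view: sum along y, rows = z (long axis), cols = x."""
    grid.require_cubic()
    return Image2D(grid.data.sum(axis=1), grid.voxel_size,
                   meta={"orientation": "side (sum over y)"})


# ---------------------------------------------------------------------------
# Projection matching
# ---------------------------------------------------------------------------

def orientation_grid(angular_step: float, include_gamma: bool = True):
    """Approximately uniform zyz orientations with cos(beta)-uniform tilts.

    Beta values sample ``cos(beta)`` uniformly on [1, -1]; the azimuth count
    per tilt ring scales with ``sin(beta)``.  The identity orientation is
    always included first.  Deterministic ordering.
    """
    if angular_step <= 0:
        raise ValueError("angular_step must be positive")
    n_beta = max(int(round(180.0 / angular_step)) + 1, 2)
    betas = np.degrees(np.arccos(np.linspace(1.0, -1.0, n_beta)))
    gammas = (np.arange(max(int(round(360.0 / angular_step)), 1))
              * angular_step) if include_gamma else np.array([0.0])
    orientations = []
    for beta in betas:
        n_alpha = max(int(round(360.0 * math.sin(math.radians(beta))
                                / angular_step)), 1)
        alphas = np.arange(n_alpha) * 360.0 / n_alpha
        for alpha in alphas:
            for gamma in gammas:
                orientations.append((float(alpha), float(beta), float(gamma)))
    return orientations


def _ncc_with_shift(image: np.ndarray, template: np.ndarray) -> float:
    """Max normalized cross-correlation over circular in-plane shifts."""
    a = image - image.mean()
    b = template - template.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    cc = np.fft.ifftn(np.fft.fftn(a) * np.conj(np.fft.fftn(b))).real
    return float(cc.max() / (na * nb))


@dataclass
class MatchResult:
    orientation: tuple
    score: float
    table: list  # (alpha, beta, gamma, score) rows, scan order


def match_projections(image: Image2D, grid: VoxelGrid,
                      angular_step: float = 15.0,
                      resample: bool = False) -> MatchResult:
    """Exhaustively match an image against projections of a volume.

    Scores every orientation on an approximately uniform grid by maximum
    shift-searched NCC (in-plane rotation is folded into the gamma axis of
    the orientation grid).  Returns the best orientation, its score, and
    the full score table.
    """
    if angular_step > 30:
        raise ValueError("angular_step must be <= 30 degrees")
    if abs(image.pixel_size - grid.voxel_size) > 1e-6 * grid.voxel_size:
        if not resample:
            raise ValueError(
                f"pixel size {image.pixel_size} != voxel size "
                f"{grid.voxel_size}; pass resample=True")
        zoom = image.pixel_size / grid.voxel_size
        data = ndimage.zoom(image.data, zoom, order=1)
        image = Image2D(data, grid.voxel_size)
    n = grid.data.shape[0]
    img = image.data
    if img.shape[0] != n:
        # center-crop or pad the image to the grid side
        out = np.zeros((n, n))
        s = min(n, img.shape[0])
        a0 = (img.shape[0] - s) // 2
        b0 = (n - s) // 2
        out[b0:b0 + s, b0:b0 + s] = img[a0:a0 + s, a0:a0 + s]
        img = out

    table = []
    best = None
    for euler in orientation_grid(angular_step):
        proj = project(grid, euler).data
        score = _ncc_with_shift(img, proj)
        table.append((*euler, score))
        if best is None or score > best[1]:
            best = (euler, score)
    return MatchResult(orientation=best[0], score=best[1], table=table)
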