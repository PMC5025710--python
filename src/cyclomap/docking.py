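"""Rigid-body fitting of atomic models into density maps by FFT correlation.

The probe is rendered as a Gaussian-atom density at the stated resolution,
scanned over a deterministic orientation grid, and translated exhaustively
via FFT cross-correlation.  Top hits are refined with bounded line searches
on the Euler angles and sub-voxel parabolic interpolation on the shift.
Six-copy sequential fitting masks out each placed copy before refitting and
reports steric clashes between placed copies.  There is no randomness
anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .density_model import model_to_density, orientation_grid, rotation_matrix
from .map_core import AtomicModel, VoxelGrid

__all__ = [
    "RigidPose",
    "FitResult",
    "cross_correlate_translations",
    "peak_shift",
    "rigid_fit",
    "sequential_multifit",
    "clash_count",
]


@dataclass
class RigidPose:
    """Rotation (zyz Euler, degrees) + translation of a probe's COM.

    The pose maps the COM-centered probe into the map frame:
    ``placed = R @ (coords - com) + translation`` with the translation
    measured in Angstrom from the box center, ``(x, y, z)`` order.
    """

    euler_zyz_deg: tuple
    translation: tuple = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.euler_zyz_deg)

    def canonical(self) -> "RigidPose":
        """Normalize angles: alpha, gamma in [0, 360), beta in [0, 180]."""
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Gimbal lock")
            a, b, g = Rotation.from_matrix(self.matrix).as_euler(
                "ZYZ", degrees=True)
        return RigidPose((a % 360.0, b, g % 360.0), tuple(self.translation))

    def inverse(self) -> "RigidPose":
        Rinv = self.matrix.T
        t = -Rinv @ np.asarray(self.translation)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Gimbal lock")
            a, b, g = Rotation.from_matrix(Rinv).as_euler("ZYZ", degrees=True)
        return RigidPose((a % 360.0, b, g % 360.0), tuple(t))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.matrix.T + np.asarray(self.translation)

    def place(self, model: AtomicModel) -> AtomicModel:
        """Apply the pose to a model (centered on its COM first)."""
        centered = model.centered()
        return centered.transformed(self.matrix, np.asarray(self.translation))


@dataclass
class FitResult:
    pose: RigidPose
    score: float
    rank: int = 0
    clash_count: int = 0
    meta: dict = field(default_factory=dict)


def _zero_mean(data: np.ndarray) -> np.ndarray:
    return data - data.mean()


def cross_correlate_translations(map_grid: VoxelGrid,
                                 probe: VoxelGrid) -> np.ndarray:
    """Normalized cross-correlation over all (circular) translations.

    ``cc[t]`` is the NCC between the map and the probe translated by ``t``
    voxels (index order ``(z, y, x)``, wrap-around); the peak value equals
    the direct-space NCC at that shift.
    """
    if map_grid.data.shape != probe.data.shape:
        raise ValueError(
            f"box mismatch {map_grid.data.shape} vs {probe.data.shape}")
    if abs(map_grid.voxel_size - probe.voxel_size) > 1e-6 * map_grid.voxel_size:
        raise ValueError("voxel size mismatch")
    m = _zero_mean(map_grid.data)
    p = _zero_mean(probe.data)
    nm = np.linalg.norm(m)
    npr = np.linalg.norm(p)
    if nm == 0:
        raise ValueError("map has zero variance")
    if npr == 0:
        raise ValueError("probe has zero variance")
    cc = np.fft.ifftn(np.fft.fftn(m) * np.conj(np.fft.fftn(p))).real
    return cc / (nm * npr)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if abs(denom) < 1e-30:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def peak_shift(cc: np.ndarray, subvoxel: bool = True):
    """Locate the correlation peak; return (score, signed shift in voxels).

    The shift is in index order ``(z, y, x)``; sub-voxel refinement fits a
    parabola through the peak and its circular neighbors per axis.
    """
    idx = np.unravel_index(np.argmax(cc), cc.shape)
    score = float(cc[idx])
    shift = np.array(idx, dtype=float)
    if subvoxel:
        for ax, i in enumerate(idx):
            sel = list(idx)
            sel[ax] = (i - 1) % cc.shape[ax]
            cm = cc[tuple(sel)]
            sel[ax] = (i + 1) % cc.shape[ax]
            cp = cc[tuple(sel)]
            shift[ax] += _parabolic_offset(cm, score, cp)
    for ax, n in enumerate(cc.shape):
        if shift[ax] > n / 2:
            shift[ax] -= n
    return score, shift


def _render_rotated(model: AtomicModel, euler, voxel_size: float,
                    resolution: float, box: int) -> VoxelGrid:
    rotated = model.transformed(rotation=rotation_matrix(euler))
    return model_to_density(rotated, voxel_size, resolution, box,
                            strict_bounds=False)


def _score_orientation(Fm: np.ndarray, nm: float, model: AtomicModel, euler,
                       voxel_size: float, resolution: float, box: int):
    probe = _render_rotated(model, euler, voxel_size, resolution, box)
    p = _zero_mean(probe.data)
    npr = np.linalg.norm(p)
    if npr == 0:
        return -np.inf, np.zeros(3)
    cc = np.fft.ifftn(Fm * np.conj(np.fft.fftn(p))).real / (nm * npr)
    return peak_shift(cc)


def rigid_fit(map_grid: VoxelGrid, model: AtomicModel,
              angular_step: float = 10.0, resolution: float = 15.0,
              n_best: int = 1, refine: bool = True) -> list:
    """Exhaustive rigid-body fit of a model into a map.

    Returns ``n_best`` :class:`FitResult` objects sorted by score
    (descending; ties broken by lexicographic Euler order).  Fully
    deterministic.
    """
    map_grid.require_cubic()
    if not 5.0 <= angular_step <= 30.0:
        raise ValueError("angular_step must be in [5, 30] degrees")
    m = _zero_mean(map_grid.data)
    nm = np.linalg.norm(m)
    if nm == 0:
        raise ValueError("map has zero variance")
    Fm = np.fft.fftn(m)
    box = map_grid.data.shape[0]
    vs = map_grid.voxel_size
    centered = model.centered()

    scored = []
    for euler in orientation_grid(angular_step):
        score, shift = _score_orientation(Fm, nm, centered, euler, vs,
                                          resolution, box)
        scored.append((score, euler, shift))
    # sort by descending score, ties by lexicographic Euler triple
    scored.sort(key=lambda rec: (-rec[0], rec[1]))

    results = []
    for rank, (score, euler, shift) in enumerate(scored[:n_best]):
        if refine:
            score, euler, shift = _refine_angles(
                Fm, nm, centered, euler, vs, resolution, box,
                half_width=angular_step / 2.0)
        translation = tuple(shift[::-1] * vs)  # (z,y,x) voxels -> (x,y,z) A
        pose = RigidPose(tuple(euler), translation).canonical()
        results.append(FitResult(pose=pose, score=score, rank=rank,
                                 meta={"angular_step": angular_step,
                                       "resolution": resolution}))
    return results


def _refine_angles(Fm, nm, model, euler, voxel_size, resolution, box,
                   half_width: float, sweeps: int = 2):
    """Coordinate-wise bounded line search on the three Euler angles."""
    euler = list(euler)

    def value(angles):
        return _score_orientation(Fm, nm, model, angles, voxel_size,
                                  resolution, box)[0]

    for _ in range(sweeps):
        for ax in range(3):
            lo = euler[ax] - half_width
            hi = euler[ax] + half_width

            def neg(a, ax=ax):
                trial = list(euler)
                trial[ax] = a
                return -value(trial)

            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 0.05})
            if -res.fun >= value(euler):
                euler[ax] = float(res.x)
    score, shift = _score_orientation(Fm, nm, model, euler, voxel_size,
                                      resolution, box)
    return score, tuple(euler), shift


def clash_count(coords_a, coords_b, cutoff: float = 2.0) -> int:
    """Number of inter-model atom pairs closer than ``cutoff`` Angstrom."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    return int(tree_a.count_neighbors(tree_b, cutoff, cumulative=True))


def _placed_mask(rendered: np.ndarray, dilate_px: int = 2,
                 soft_sigma: float = 1.0) -> np.ndarray:
    """Soft mask of a placed copy: half-max support dilated then smoothed."""
    binary = rendered >= 0.5 * rendered.max()
    if dilate_px > 0:
        binary = ndimage.binary_dilation(binary, iterations=dilate_px)
    soft = ndimage.gaussian_filter(binary.astype(float), soft_sigma)
    return np.clip(soft, 0.0, 1.0)


def sequential_multifit(map_grid: VoxelGrid, model: AtomicModel,
                        n_copies: int = 6, angular_step: float = 10.0,
                        resolution: float = 15.0,
                        score_floor: float = 0.1,
                        clash_cutoff: float = 2.0) -> list:
    """Fit ``n_copies`` of a model, masking each placed copy before refitting.

    Returns the placed :class:`FitResult` list in placement order; each
    result carries the clash count of its copy against all previously
    placed copies.  Stops early (with a warning) if the best remaining
    score drops below ``score_floor``.
    """
    current = map_grid.copy()
    box = map_grid.data.shape[0]
    vs = map_grid.voxel_size
    placed = []
    placed_coords = []
    for i in range(n_copies):
        hits = rigid_fit(current, model, angular_step=angular_step,
                         resolution=resolution, n_best=1)
        fit = hits[0]
        if fit.score < score_floor:
            warnings.warn(
                f"only {i} of {n_copies} copies placed; best remaining "
                f"score {fit.score:.3f} below floor {score_floor}",
                stacklevel=2)
            break
        placed_model = fit.pose.place(model)
        clashes = sum(clash_count(placed_model.coords, prev, clash_cutoff)
                      for prev in placed_coords)
        fit = FitResult(pose=fit.pose, score=fit.score, rank=i,
                        clash_count=clashes, meta=fit.meta)
        rendered = model_to_density(placed_model, vs, resolution, box,
                                    strict_bounds=False)
        current = VoxelGrid(current.data * (1.0 - _placed_mask(rendered.data)),
                            vs, map_grid.origin)
        placed.append(fit)
        placed_coords.append(placed_model.coords)
    return placed
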