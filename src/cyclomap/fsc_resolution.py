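"""Fourier shell correlation, threshold-crossing resolution, soft masks.

FSC between two maps is the per-shell normalized complex correlation
``Re<A . B*> / sqrt(<|A|^2><|B|^2>)`` over concentric Fourier shells; the
resolution is the reciprocal of the first downward crossing of a threshold
(0.143 by the gold-standard convention for half maps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .map_core import VoxelGrid, _radial_freq_pixels

__all__ = ["FSCCurve", "fsc", "resolution_at_threshold", "soft_mask"]


@dataclass
class FSCCurve:
    """Per-shell correlation between two maps."""

    freq: np.ndarray          # shell centers, 1/Angstrom
    correlation: np.ndarray   # in [-1, 1]
    n_voxels: np.ndarray      # Fourier samples per shell
    voxel_size: float
    shell_width: float        # Fourier pixels
    zero_power_shells: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.freq)


def shell_indices(shape, shell_width: float = 1.0):
    """Shell id per (unshifted) Fourier sample; DC gets shell -1."""
    r = _radial_freq_pixels(shape)
    shells = np.floor((r - 0.5) / shell_width).astype(int)
    shells[r < 0.5] = -1
    return shells


def fsc(a: VoxelGrid, b: VoxelGrid, shell_width: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two same-sized maps.

    DC is excluded from the first shell.  Shells with zero power in either
    map are recorded as correlation 0 and flagged in
    ``zero_power_shells``.
    """
    if a.data.shape != b.data.shape:
        raise ValueError(f"box mismatch {a.data.shape} vs {b.data.shape}")
    if abs(a.voxel_size - b.voxel_size) > 1e-6 * a.voxel_size:
        raise ValueError("voxel size mismatch")
    n = a.data.shape[0]
    A = np.fft.fftn(a.data)
    B = np.fft.fftn(b.data)
    shells = shell_indices(a.data.shape, shell_width)
    n_shells = int(n // 2 / shell_width)
    flat = shells.ravel()
    valid = (flat >= 0) & (flat < n_shells)
    idx = flat[valid]

    cross = np.bincount(idx, weights=(A * np.conj(B)).real.ravel()[valid],
                        minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(A) ** 2).ravel()[valid],
                     minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(B) ** 2).ravel()[valid],
                     minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)

    corr = np.zeros(n_shells)
    zero_power = []
    nonzero = (pa > 0) & (pb > 0)
    corr[nonzero] = cross[nonzero] / np.sqrt(pa[nonzero] * pb[nonzero])
    for s in np.where(~nonzero)[0]:
        zero_power.append(int(s))
    # shell center radius (Fourier px) -> spatial frequency (1/A)
    centers = (np.arange(n_shells) + 1.0) * shell_width
    freq = centers / (n * a.voxel_size)
    return FSCCurve(freq=freq, correlation=np.clip(corr, -1.0, 1.0),
                    n_voxels=counts, voxel_size=a.voxel_size,
                    shell_width=shell_width, zero_power_shells=zero_power)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (Angstrom) at the first downward crossing of ``threshold``.

    The crossing frequency is linearly interpolated between the adjacent
    shells.  A curve that never drops below the threshold yields the
    Nyquist resolution (with a warning); one that starts below it is an
    error.
    """
    c = curve.correlation
    f = curve.freq
    if c[0] < threshold:
        raise ValueError(
            f"FSC starts below threshold ({c[0]:.3f} < {threshold})")
    below = np.where(c < threshold)[0]
    if len(below) == 0:
        warnings.warn("FSC never drops below threshold; returning Nyquist",
                      stacklevel=2)
        return 2.0 * curve.voxel_size
    i = below[0]
    f0, f1 = f[i - 1], f[i]
    c0, c1 = c[i - 1], c[i]
    cross = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
    return float(1.0 / cross)


def soft_mask(grid: VoxelGrid, level_fraction: float = 0.02,
              extend_px: int = 3, soft_edge_px: int = 6) -> VoxelGrid:
    """Binarize-dilate-soften mask in [0, 1] around the particle support.

    Binarizes at ``level_fraction * max``, dilates by ``extend_px`` voxels,
    then applies a cosine falloff over ``soft_edge_px`` voxels.
    """
    data = grid.data
    peak = data.max()
    if peak <= 0:
        raise ValueError("cannot mask a map with no positive density")
    binary = data >= level_fraction * peak
    if not binary.any():
        raise ValueError("mask is empty at the requested level")
    if extend_px > 0:
        binary = ndimage.binary_dilation(binary, iterations=extend_px)
    mask = binary.astype(float)
    if soft_edge_px > 0:
        dist = ndimage.distance_transform_edt(~binary)
        edge = (dist > 0) & (dist <= soft_edge_px)
        mask[edge] = 0.5 * (1.0 + np.cos(np.pi * dist[edge] / soft_edge_px))
        mask[dist > soft_edge_px] = 0.0
    return VoxelGrid(mask, grid.voxel_size, grid.origin,
                     meta={"mask": {"level_fraction": level_fraction,
                                    "extend_px": extend_px,
                                    "soft_edge_px": soft_edge_px}})
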