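"""Cylindrically symmetric 3D initial models from a single 2D side view.

The central operation, :func:`cylindrize`, sweeps the 2D Fourier transform
of a (centered, vertically aligned) side-view image about the vertical axis
to fill a 3D Fourier volume, then inverse-transforms it.  At each axial
frequency level the 2D spectral profile is evaluated at the in-plane radius
``sqrt(kx^2 + ky^2)`` by linear interpolation between adjacent sampled
radii; radii beyond the 2D support are set to zero.

The input image is mirror-symmetrized about the long axis by default so the
rotated spectrum satisfies Friedel symmetry and the inverse transform is
real.  A :func:`soft_cylinder` generator provides the rotationally
symmetric control model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .map_core import Image2D, VoxelGrid, low_pass_filter

__all__ = [
    "SymmetrizationParams",
    "center_and_align",
    "cylindrize",
    "soft_cylinder",
    "make_initial_model",
    "profile_fwhm",
    "axial_fwhm",
]


def profile_fwhm(profile: np.ndarray, spacing: float = 1.0) -> float:
    """Full width at half maximum of a 1D profile, Angstrom.

    Half-max crossings are located by linear interpolation between samples.
    """
    profile = np.asarray(profile, dtype=float)
    half = profile.max() / 2.0
    above = np.where(profile >= half)[0]
    if len(above) == 0:
        raise ValueError("profile has no samples above half max")
    lo, hi = above[0], above[-1]
    left = float(lo)
    if lo > 0:
        left = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
    right = float(hi)
    if hi < len(profile) - 1:
        right = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
    return (right - left) * spacing


def axial_fwhm(grid: VoxelGrid) -> float:
    """FWHM (Angstrom) of the on-axis density profile along z."""
    c = grid.data.shape[1] // 2
    return profile_fwhm(grid.data[:, c, c], grid.voxel_size)


@dataclass
class SymmetrizationParams:
    """Knobs for the side-view -> cylindrical-model pipeline."""

    pre_lowpass: float = 120.0          # Angstrom
    final_lowpass: float = 120.0        # Angstrom, applied after sweeping
    mirror_symmetrize: bool = True
    center_method: str = "com"          # "com" | "mirror-cc"
    asymmetry_tolerance: float = 1e-3   # complex residue warning threshold

    def validate(self, pixel_size: float) -> None:
        if self.pre_lowpass < 2.0 * pixel_size:
            raise ValueError("pre_lowpass below the Nyquist limit")
        if self.center_method not in ("com", "mirror-cc"):
            raise ValueError(f"unknown center_method {self.center_method!r}")


def _moments(data: np.ndarray):
    """COM (row, col) and 2x2 covariance of non-negative image weights."""
    total = data.sum()
    zz, xx = np.indices(data.shape)
    cz = (zz * data).sum() / total
    cx = (xx * data).sum() / total
    dz, dx = zz - cz, xx - cx
    cov = np.array([
        [(dz * dz * data).sum(), (dz * dx * data).sum()],
        [(dx * dz * data).sum(), (dx * dx * data).sum()],
    ]) / total
    return (cz, cx), cov


def _fourier_shift(data: np.ndarray, shift) -> np.ndarray:
    """Subpixel translation by Fourier phase ramp (exact for band-limited)."""
    return ndimage.fourier_shift(np.fft.fftn(data), shift)


def center_and_align(image: Image2D) -> Image2D:
    """Center the particle and align its principal axis with the vertical.

    Background is taken as the image median; negative values are clamped to
    zero for the moment computation only.  Translation is applied with a
    Fourier phase ramp, rotation with bicubic interpolation.
    """
    data = image.data
    weights = np.clip(data - np.median(data), 0.0, None)
    if weights.sum() <= 0:
        raise ValueError("image is empty after background subtraction")
    (cz, cx), cov = _moments(weights)

    # rotate major principal axis onto the vertical (row) axis
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]          # (d_row, d_col)
    angle = np.degrees(np.arctan2(major[1], major[0]))
    if angle > 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0

    n = data.shape[0]
    center = n // 2
    shifted = np.fft.ifftn(_fourier_shift(data, (center - cz, center - cx))).real
    if abs(angle) > 1e-9:
        aligned = ndimage.rotate(shifted, -angle, axes=(0, 1), reshape=False,
                                 order=3, mode="constant", cval=0.0)
    else:
        aligned = shifted
    meta = dict(image.meta)
    meta["alignment"] = {
        "shift_px": (center - cz, center - cx),
        "rotation_deg": angle,
        "interpolation": "fourier-shift + bicubic rotation",
    }
    return Image2D(aligned, image.pixel_size, meta)


def _even_pad(data: np.ndarray) -> np.ndarray:
    """Force an even side length by zero-padding one row/column per odd axis."""
    pads = [(0, s % 2) for s in data.shape]
    if any(p[1] for p in pads):
        data = np.pad(data, pads)
    return data


def cylindrize(image: Image2D,
               params: SymmetrizationParams | None = None) -> VoxelGrid:
    """Extend a centered side view to a rotationally symmetric 3D volume.

    Returns a cubic :class:`VoxelGrid` with the image's side length and
    pixel size.  The output is exactly invariant under the mirror
    ``x -> -x`` and rotationally invariant about z up to interpolation.
    """
    params = params or SymmetrizationParams()
    params.validate(image.pixel_size)
    data = _even_pad(np.asarray(image.data, dtype=np.float64))
    n = data.shape[0]
    if data.shape[0] != data.shape[1]:
        raise ValueError("cylindrize requires a square image")
    c = n // 2

    if params.mirror_symmetrize:
        # mirror about the center column c (j -> 2c - j mod n, even n)
        data = 0.5 * (data + np.roll(data[:, ::-1], 1, axis=1))

    # centered 2D spectrum: rows = kz, cols = kx
    spec2 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(data)))

    # radial profile per kz level: prof[iz, r] for r = 0..c
    prof = np.zeros((n, c + 1), dtype=complex)
    prof[:, : n - c] = spec2[:, c:]
    prof[:, c] = spec2[:, 0]  # Nyquist column (kx = -n/2 aliases +n/2)

    # in-plane radius of every (ky, kx) sample of the centered 3D spectrum
    ky, kx = np.indices((n, n)) - c
    radius = np.hypot(ky, kx)
    r0 = np.floor(radius).astype(int)
    frac = radius - r0
    r1 = r0 + 1
    valid0 = r0 <= c
    valid1 = r1 <= c
    r0c = np.where(valid0, r0, 0)
    r1c = np.where(valid1, r1, 0)

    spec3 = np.empty((n, n, n), dtype=complex)
    for iz in range(n):
        p = prof[iz]
        plane = (1.0 - frac) * np.where(valid0, p[r0c], 0.0) \
            + frac * np.where(valid1, p[r1c], 0.0)
        spec3[iz] = plane

    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec3)))
    rms = np.sqrt(np.mean(np.abs(vol) ** 2))
    residue = np.sqrt(np.mean(vol.imag ** 2)) / max(rms, 1e-30)
    if residue > params.asymmetry_tolerance:
        warnings.warn(
            f"complex residue {residue:.2e} after cylindrization; input may "
            "not be mirror-symmetric", stacklevel=2)
    meta = dict(image.meta)
    meta["cylindrize"] = {"mirror_symmetrize": params.mirror_symmetrize,
                          "complex_residue": float(residue)}
    return VoxelGrid(vol.real, image.pixel_size, meta=meta)


def soft_cylinder(length: float, diameter: float, box: int, voxel_size: float,
                  edge_width: float = 10.0) -> VoxelGrid:
    """Generate a soft-edged cylinder of the given physical dimensions.

    Density is 1 inside, 0 outside, with a cosine ramp of ``edge_width``
    Angstrom centered on the nominal surface (value exactly 0.5 at the
    surface).  The axial and radial profiles are separable (multiplied).
    """
    extent = box * voxel_size
    if length + edge_width > extent or diameter + edge_width > extent:
        raise ValueError(
            f"cylinder ({length} x {diameter} A) plus edge {edge_width} A "
            f"exceeds box extent {extent} A")

    c = box // 2
    coords = (np.arange(box) - c) * voxel_size

    def ramp(dist_from_surface):
        # dist < -e/2: inside (1); dist > e/2: outside (0)
        if edge_width <= 0:
            return (dist_from_surface < 0).astype(float)
        t = np.clip(dist_from_surface / edge_width + 0.5, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))

    axial = ramp(np.abs(coords) - length / 2.0)                  # (z,)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    radial = ramp(np.hypot(yy, xx) - diameter / 2.0)             # (y, x)
    data = axial[:, None, None] * radial[None, :, :]
    return VoxelGrid(data, voxel_size,
                     meta={"soft_cylinder": {"length": length,
                                             "diameter": diameter,
                                             "edge_width": edge_width}})


def make_initial_model(image: Image2D,
                       params: SymmetrizationParams | None = None) -> VoxelGrid:
    """Full pipeline: align -> pre-lowpass -> cylindrize -> final lowpass."""
    params = params or SymmetrizationParams()
    params.validate(image.pixel_size)

    rel_std = image.data.std() / max(np.abs(image.data).max(), 1e-30)
    if rel_std < 1e-6:
        warnings.warn("input image is (nearly) constant; the model will be "
                      "a featureless rod", stacklevel=2)
        aligned = image
    else:
        aligned = center_and_align(image)
    filtered = low_pass_filter(aligned, params.pre_lowpass)
    grid = cylindrize(filtered, params)
    grid = low_pass_filter(grid, params.final_lowpass)
    grid.meta["initial_model"] = {
        "pre_lowpass_A": params.pre_lowpass,
        "final_lowpass_A": params.final_lowpass,
        "mirror_symmetrize": params.mirror_symmetrize,
    }
    return grid
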