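"""Synthetic fixtures: hexamer phantoms, noisy projections, SSNR half-maps.

The hexamer phantom mimics a head-neck-legs particle: a six-subunit
"head" ring (closed planar or lock-washer with programmable opening angle
and total rise), a short trimeric "neck", and three pairs of "legs" in a
trimer-of-dimers arrangement.  Each subunit is a rigid cluster of Gaussian
blobs, so every generator returns exact ground-truth poses and anchors for
recovery tests.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .density_model import project
from .fsc_resolution import shell_indices
from .map_core import Image2D, VoxelGrid

__all__ = [
    "PhantomSpec",
    "hexamer_ground_truth",
    "make_hexamer_phantom",
    "make_projection_set",
    "make_half_maps",
]


@dataclass
class PhantomSpec:
    """Geometry of the synthetic hexameric head-neck-legs particle."""

    conformation: str = "planar"      # "planar" | "lockwasher"
    opening_angle: float = 60.0       # deg, largest azimuthal gap
    total_rise: float = 0.0           # Angstrom across the gap pair
    head_length: float = 90.0
    head_width: float = 143.0
    neck_width: float = 93.0
    neck_length: float = 10.0
    channel_diameter: float = 15.0
    c_gate_diameter: float = 20.0
    total_length: float = 230.0
    box: int = 112
    voxel_size: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.conformation not in ("planar", "lockwasher"):
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.conformation == "lockwasher" and self.opening_angle < 60.0:
            raise ValueError("lockwasher opening_angle must be >= 60 degrees")
        extent = self.box * self.voxel_size
        if self.total_length + abs(self.total_rise) + 10 > extent:
            raise ValueError(
                f"particle length {self.total_length} A (+rise) exceeds box "
                f"extent {extent} A")
        if self.head_width + 10 > extent:
            raise ValueError("head width exceeds box extent")


# rigid local blob cluster for one head subunit: (radial, tangential, axial)
# offsets in units of the subunit size; deterministic and asymmetric enough
# for pose recovery.
_SUBUNIT_BLOBS = np.array([
    #  dr,    dt,    dz,   relative weight
    [0.00,  0.00,  0.30, 1.0],
    [0.00,  0.00, -0.30, 1.0],
    [0.35,  0.20,  0.00, 0.8],
    [-0.35, -0.10,  0.10, 0.8],
    [0.10, -0.40, -0.15, 0.7],
    [-0.15,  0.40,  0.20, 0.7],
    [0.25, -0.15,  0.45, 0.5],
    [-0.25,  0.15, -0.45, 0.5],
])


def _subunit_azimuths_and_heights(spec: PhantomSpec):
    """Azimuth (deg) and axial offset (Angstrom) of the six head subunits.

    Subunit 0 sits just after the ring gap; the gap lies between subunit 5
    and subunit 0 (wrap).  For the planar conformation all gaps are 60 deg
    and the rise is zero.

    Lock-washer heights follow a helical ramp made orthogonal to the
    constant and first-harmonic azimuthal components, so the
    total-least-squares plane through the anchors stays horizontal: the
    programmed opening angle and gap-pair axial difference are then
    recovered *exactly* by the ring-geometry fit.
    """
    if spec.conformation == "planar":
        gaps = np.full(5, 60.0)
        azimuths = np.concatenate([[0.0], np.cumsum(gaps)])
        return azimuths, azimuths.copy(), np.zeros(6)

    # centroid-relative target gaps; solve for circle angles whose
    # *centroid-measured* azimuthal gaps equal the programmed ones
    target = np.append(np.full(5, (360.0 - spec.opening_angle) / 5.0),
                       spec.opening_angle)
    phi = np.concatenate([[0.0], np.cumsum(target[:-1])])
    for _ in range(200):
        x = np.cos(np.radians(phi))
        y = np.sin(np.radians(phi))
        az = np.degrees(np.arctan2(y - y.mean(), x - x.mean()))
        az = (az - az[0]) % 360.0
        gaps = np.diff(np.append(az, 360.0))
        err = target[:-1] - gaps[:-1]
        if np.abs(err).max() < 1e-10:
            break
        phi[1:] += np.cumsum(err)
    azimuths = (np.degrees(np.arctan2(y - y.mean(), x - x.mean()))
                - np.degrees(np.arctan2(y[0] - y.mean(), x[0] - x.mean())))
    azimuths %= 360.0

    ramp = -np.arange(6, dtype=float)  # descending: subunit 0 on top
    basis = np.column_stack([np.ones(6), x - x.mean(), y - y.mean()])
    coeffs, *_ = np.linalg.lstsq(basis, ramp, rcond=None)
    resid = ramp - basis @ coeffs
    d = resid[0] - resid[5]
    if abs(d) < 1e-9:
        raise ValueError("degenerate lock-washer geometry")
    rises = resid * (spec.total_rise / d)
    return phi, azimuths, rises


def hexamer_ground_truth(spec: PhantomSpec):
    """Exact subunit placements without rendering any density.

    Returns a dict with per-subunit ``azimuth_deg``, ``z_offset`` and the
    ``anchors`` array ((6, 3) xyz Angstrom, box-center origin) used by the
    ring-geometry metrics.
    """
    spec.validate()
    placement, azimuths, rises = _subunit_azimuths_and_heights(spec)
    z_head = spec.total_length / 2.0 - spec.head_length / 2.0
    sub_radius = spec.head_width / 2.0 * 0.62  # anchor ring radius
    anchors = np.stack([
        sub_radius * np.cos(np.radians(placement)),
        sub_radius * np.sin(np.radians(placement)),
        z_head + rises,
    ], axis=1)
    return {"placement_deg": placement, "azimuth_deg": azimuths,
            "z_offset": z_head + rises, "anchors": anchors, "spec": spec}


def _add_gaussian(data, center_xyz, sigma, weight, voxel_size):
    """Accumulate one isotropic Gaussian blob (center in Angstrom, xyz)."""
    n = data.shape[0]
    c = n // 2
    pos = np.asarray(center_xyz)[::-1] / voxel_size + c  # (z, y, x) voxels
    s = sigma / voxel_size
    half = int(math.ceil(4 * s))
    slices = []
    axes = []
    for ax in range(3):
        i0 = int(round(pos[ax]))
        lo, hi = max(i0 - half, 0), min(i0 + half + 1, n)
        if lo >= hi:
            return
        idx = np.arange(lo, hi)
        axes.append(np.exp(-0.5 * ((idx - pos[ax]) / s) ** 2))
        slices.append(slice(lo, hi))
    data[tuple(slices)] += weight * (axes[0][:, None, None]
                                     * axes[1][None, :, None]
                                     * axes[2][None, None, :])


def make_hexamer_phantom(spec: PhantomSpec | None = None):
    """Render the hexamer phantom; returns ``(VoxelGrid, ground_truth)``.

    Ground truth contains the exact subunit azimuths, axial offsets and
    anchor points of the generating geometry.
    """
    spec = spec or PhantomSpec()
    truth = hexamer_ground_truth(spec)
    n = spec.box
    vs = spec.voxel_size

    L = spec.total_length
    z_top = L / 2.0
    z_head_bot = z_top - spec.head_length
    sub_size = spec.head_length / 2.0
    blob_sigma = sub_size * 0.30
    ring_r = spec.head_width / 2.0 * 0.62
    # place the topmost blob so the head's half-max crossing lands at z_top;
    # the 0.9 sigma offset is calibrated against the overlap-normalized
    # profile (a lone Gaussian would need 1.1774 sigma)
    cap_dz = (z_top - 0.9 * blob_sigma - (z_head_bot + spec.head_length / 2.0)
              ) / sub_size

    head = np.zeros((n, n, n))
    for az, zc in zip(truth["placement_deg"], truth["z_offset"]):
        a = math.radians(az)
        e_r = np.array([math.cos(a), math.sin(a), 0.0])
        e_t = np.array([-math.sin(a), math.cos(a), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        center = ring_r * e_r + np.array([0.0, 0.0, zc])
        blobs = np.vstack([_SUBUNIT_BLOBS,
                           [0.05, 0.0, cap_dz, 2.0],       # top cap
                           [-0.05, 0.0, -cap_dz, 0.95]])    # bottom cap
        for dr, dt, dz, w in blobs:
            pos = center + sub_size * (dr * e_r + dt * e_t + dz * e_z)
            _add_gaussian(head, pos, blob_sigma, w, vs)
    head /= head.max()

    lower = np.zeros((n, n, n))
    # neck: three rods of stacked small blobs
    neck_r = spec.neck_width / 2.0 * 0.55
    neck_sigma = 6.0
    z_neck = np.linspace(z_head_bot - spec.neck_length, z_head_bot, 3)
    for k in range(3):
        a = math.radians(120.0 * k + 60.0)
        for zc in z_neck:
            _add_gaussian(lower, (neck_r * math.cos(a), neck_r * math.sin(a),
                                  zc), neck_sigma, 0.6, vs)

    # legs: three pairs of tiered blobs down to the bottom of the particle
    leg_top = z_head_bot - spec.neck_length
    leg_len = leg_top - (-L / 2.0)
    leg_sigma = leg_len * 0.14
    leg_r = spec.head_width / 2.0 * 0.45
    pair_split = 12.0  # Angstrom between the two legs of a pair
    z_bottom_blob = -L / 2.0 + 1.15 * leg_sigma  # calibrated end cap
    for k in range(3):
        a = math.radians(120.0 * k + 60.0)
        e_r = np.array([math.cos(a), math.sin(a), 0.0])
        e_t = np.array([-math.sin(a), math.cos(a), 0.0])
        for sgn in (-1.0, 1.0):
            base = leg_r * e_r + sgn * (pair_split / 2.0) * e_t
            zs = np.linspace(leg_top - 0.2 * leg_len, z_bottom_blob, 3)
            for zc, w in zip(zs, (0.9, 0.85, 1.4)):
                pos = base + np.array([0.0, 0.0, zc])
                _add_gaussian(lower, pos, leg_sigma, w, vs)
    lower /= lower.max()

    data = head + lower
    data /= data.max()

    grid = VoxelGrid(data, vs, meta={"phantom": {
        "conformation": spec.conformation,
        "opening_angle": spec.opening_angle,
        "total_rise": spec.total_rise,
        "seed": spec.seed,
    }})
    return grid, truth


def make_projection_set(grid: VoxelGrid, n: int, orientations=None,
                        snr: float = math.inf, seed: int = 0):
    """Noisy projection images with known orientations.

    ``orientations`` may be an explicit list of zyz Euler triples (degrees)
    or ``None`` for seeded random orientations.  Gaussian noise is scaled
    so that the variance ratio of signal to noise *inside the particle
    support* equals ``snr``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if orientations is None:
        alphas = rng.uniform(0, 360, n)
        betas = np.degrees(np.arccos(rng.uniform(-1, 1, n)))
        gammas = rng.uniform(0, 360, n)
        orientations = list(zip(alphas, betas, gammas))
    else:
        orientations = [tuple(o) for o in orientations][:n]
        if len(orientations) != n:
            raise ValueError("need n orientations")
    images = []
    for euler in orientations:
        clean = project(grid, euler)
        data = clean.data
        if math.isinf(snr):
            noisy = data
            sigma = 0.0
        else:
            support = np.abs(data) > 0.05 * np.abs(data).max()
            sig_var = data[support].var() if support.any() else data.var()
            sigma = math.sqrt(sig_var / snr)
            noisy = data + rng.normal(0.0, sigma, data.shape)
        images.append(Image2D(noisy, grid.voxel_size,
                              meta={"euler_zyz_deg": tuple(euler),
                                    "snr": snr, "noise_sigma": sigma}))
    return images, orientations


def make_half_maps(grid: VoxelGrid, ssnr, seed: int = 0):
    """Two half maps = signal + independent noise colored to per-shell SSNR.

    ``ssnr`` is either a scalar, an array of per-shell values, or a
    callable of spatial frequency (1/Angstrom).  The noise power in each
    Fourier shell is the measured signal power divided by the requested
    SSNR, so the expected half-map FSC is ``ssnr / (ssnr + 1)`` per shell.
    """
    n = grid.data.shape[0]
    shells = shell_indices(grid.data.shape)
    n_shells = n // 2
    F = np.fft.fftn(grid.data)
    power = np.abs(F) ** 2
    flat = shells.ravel()
    valid = (flat >= 0) & (flat < n_shells)
    sig_power = np.bincount(flat[valid], weights=power.ravel()[valid],
                            minlength=n_shells)
    counts = np.bincount(flat[valid], minlength=n_shells)
    mean_sig = np.where(counts > 0, sig_power / np.maximum(counts, 1), 0.0)

    freq = (np.arange(n_shells) + 1.0) / (n * grid.voxel_size)
    if callable(ssnr):
        s = np.asarray([ssnr(f) for f in freq], dtype=float)
    else:
        s = np.broadcast_to(np.asarray(ssnr, dtype=float), (n_shells,)).copy()
    if np.any(s <= 0):
        raise ValueError("SSNR must be positive in every shell")

    # per-sample noise std in Fourier space, per shell
    target = np.sqrt(mean_sig / s)
    scale = np.zeros(grid.data.shape)
    in_range = (shells >= 0) & (shells < n_shells)
    scale[in_range] = target[shells[in_range]]

    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(2):
        white = np.fft.fftn(rng.standard_normal(grid.data.shape))
        # E|white|^2 = n^3 per sample; rescale shell-wise to the target power
        noise = np.fft.ifftn(white * scale / math.sqrt(n ** 3)).real
        halves.append(VoxelGrid(grid.data + noise, grid.voxel_size,
                                grid.origin, meta={"half_map": {"seed": seed}}))
    return halves[0], halves[1]
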