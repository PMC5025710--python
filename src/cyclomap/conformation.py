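"""Ring vs lock-washer hexamer geometry and map morphology metrics.

``ring_geometry`` fits a total-least-squares reference plane through six
per-subunit anchor points and reports azimuthal gaps, the opening angle
(largest adjacent gap), and signed axial displacements from the plane.
Map-level metrics (bending curve, cross-section extents, axial extent,
axial-gate state) binarize density with a stated threshold rule; the
threshold always travels with the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .map_core import VoxelGrid

__all__ = [
    "RingGeometry",
    "ring_geometry",
    "bending_curve",
    "section_extent",
    "axial_extent",
    "gate_state",
]


@dataclass
class RingGeometry:
    """Fitted reference plane + per-subunit ring metrics (all Angstrom/deg)."""

    anchors: np.ndarray            # (6, 3) xyz, input order
    plane_point: np.ndarray        # centroid of anchors
    plane_normal: np.ndarray       # unit normal, oriented toward +z
    azimuths: np.ndarray           # sorted ascending, degrees in [0, 360)
    order: np.ndarray              # anchor indices sorted by azimuth
    gaps: np.ndarray               # adjacent gaps (wraps), sum = 360
    gap_index: tuple               # anchor indices flanking the largest gap
    opening_angle: float           # degrees, largest adjacent gap
    axial_displacements: np.ndarray  # signed distance to plane, input order
    gap_axial_difference: float    # displacement difference across the gap
    anchor_rule: str = "provided"


def _fit_plane(points: np.ndarray):
    """Total-least-squares plane: (centroid, unit normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9:
        raise ValueError("anchors are collinear; no unique plane")
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and normal[np.abs(normal).argmax()] < 0):
        normal = -normal
    return centroid, normal


def ring_geometry(anchors, anchor_rule: str = "provided") -> RingGeometry:
    """Ring metrics from exactly six anchor points (one per subunit).

    The opening angle is the largest gap between adjacent anchor azimuths
    about the fitted plane normal; for a closed planar hexamer it is 60
    degrees.  ``gap_axial_difference`` is the signed axial displacement of
    the subunit *after* the gap (in azimuth order) minus the one before it,
    so its sign flips under a mirror.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.shape != (6, 3):
        raise ValueError(f"expected 6 anchors of 3 coordinates, got {anchors.shape}")
    dists = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=-1)
    if np.any(dists[np.triu_indices(6, 1)] < 1e-6):
        raise ValueError("coincident anchors")

    centroid, normal = _fit_plane(anchors)
    # in-plane orthonormal basis; reference direction from the first anchor
    rel = anchors - centroid
    axial = rel @ normal
    in_plane = rel - np.outer(axial, normal)
    e1 = in_plane[0] / np.linalg.norm(in_plane[0])
    e2 = np.cross(normal, e1)
    az = np.degrees(np.arctan2(in_plane @ e2, in_plane @ e1)) % 360.0

    order = np.argsort(az, kind="stable")
    az_sorted = az[order]
    gaps = np.diff(np.append(az_sorted, az_sorted[0] + 360.0))
    k = int(np.argmax(gaps))
    before = int(order[k])
    after = int(order[(k + 1) % 6])
    return RingGeometry(
        anchors=anchors,
        plane_point=centroid,
        plane_normal=normal,
        azimuths=az_sorted,
        order=order,
        gaps=gaps,
        gap_index=(before, after),
        opening_angle=float(gaps[k]),
        axial_displacements=axial,
        gap_axial_difference=float(axial[after] - axial[before]),
        anchor_rule=anchor_rule,
    )


def _threshold_level(data: np.ndarray, threshold: float,
                     absolute: bool) -> float:
    return threshold if absolute else threshold * data.max()


def bending_curve(grid: VoxelGrid, slab_thickness: float = 10.0,
                  threshold: float = 0.5, absolute: bool = False):
    """Per-z-slab center-of-mass polyline and a lateral bend score.

    The bend score is the maximum lateral (xy) deviation of slab COMs from
    the straight chord joining the first and last occupied slabs.  Empty
    slabs are skipped and recorded in ``gaps``.

    Returns a dict with ``points`` (n, 3) xyz in Angstrom (box-center
    origin), ``bend_score`` (Angstrom), and ``gaps`` (z centers of empty
    slabs).
    """
    data = grid.data
    vs = grid.voxel_size
    level = _threshold_level(data, threshold, absolute)
    nz = data.shape[0]
    c = grid.data.shape[0] // 2
    per_slab = max(int(round(slab_thickness / vs)), 1)
    points = []
    gaps = []
    for lo in range(0, nz, per_slab):
        slab = data[lo:lo + per_slab]
        mask = slab >= level
        zc = (lo + (min(lo + per_slab, nz) - lo) / 2.0 - c) * vs
        if not mask.any():
            gaps.append(zc)
            continue
        zz, yy, xx = np.nonzero(mask)
        weights = slab[zz, yy, xx]
        total = weights.sum()
        com_y = ((yy * weights).sum() / total - c) * vs
        com_x = ((xx * weights).sum() / total - c) * vs
        com_z = (((zz + lo) * weights).sum() / total - c) * vs
        points.append((com_x, com_y, com_z))
    if len(points) < 2:
        raise ValueError("fewer than two occupied slabs above threshold")
    pts = np.asarray(points)
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        dev = np.linalg.norm(pts - a, axis=1)
    else:
        u = chord / norm
        rel = pts - a
        dev = np.linalg.norm(rel - np.outer(rel @ u, u), axis=1)
    return {"points": pts, "bend_score": float(dev.max()), "gaps": gaps,
            "threshold": threshold, "absolute": absolute}


def _max_caliper(coords: np.ndarray) -> float:
    """Largest pairwise extent of a 2D point set (convex hull diameter)."""
    if len(coords) > 3:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:
            pass
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def _min_caliper(coords: np.ndarray) -> float:
    """Smallest width of the convex hull (rotating calipers over edges)."""
    if len(coords) < 3:
        return 0.0
    try:
        hull = coords[ConvexHull(coords).vertices]
    except Exception:
        return 0.0
    widths = []
    n = len(hull)
    for i in range(n):
        edge = hull[(i + 1) % n] - hull[i]
        norm = np.linalg.norm(edge)
        if norm < 1e-12:
            continue
        perp = np.array([-edge[1], edge[0]]) / norm
        proj = (hull - hull[i]) @ perp
        widths.append(proj.max() - proj.min())
    return float(min(widths)) if widths else 0.0


def section_extent(grid: VoxelGrid, z: float, threshold: float = 0.5,
                   absolute: bool = False):
    """Outer extents and lumen of a cross-section at height ``z`` (Angstrom).

    Returns a dict with ``max_diameter`` and ``min_diameter`` (caliper
    extents of the thresholded section, Angstrom) and ``lumen``: the
    equivalent diameter of the interior background component containing the
    long axis, or ``"closed"`` if the axis point lies inside density / no
    enclosed background exists.
    """
    vs = grid.voxel_size
    n = grid.data.shape[0]
    c = n // 2
    iz = int(round(z / vs + c))
    if not 0 <= iz < n:
        raise ValueError(f"z = {z} A outside the box")
    section = grid.data[iz]
    level = _threshold_level(grid.data, threshold, absolute)
    mask = section >= level
    if not mask.any():
        raise ValueError(f"empty section at z = {z} A (threshold {level:g})")
    yy, xx = np.nonzero(mask)
    coords = np.column_stack([yy, xx]).astype(float) * vs
    max_d = _max_caliper(coords) + vs  # pixel extent, not center distance
    min_d = _min_caliper(coords) + vs

    lumen = "closed"
    background = ~mask
    if background[c, c]:
        labels, _ = ndimage.label(background)
        axis_label = labels[c, c]
        comp = labels == axis_label
        touches_border = (comp[0].any() or comp[-1].any()
                          or comp[:, 0].any() or comp[:, -1].any())
        if not touches_border:
            area = comp.sum() * vs * vs
            lumen = float(2.0 * np.sqrt(area / np.pi))
    return {"max_diameter": max_d, "min_diameter": min_d, "lumen": lumen,
            "threshold": threshold, "absolute": absolute}


def axial_extent(grid: VoxelGrid, threshold: float = 0.5,
                 absolute: bool = False) -> float:
    """Extent along z (Angstrom) of density above the threshold."""
    data = grid.data
    if data.max() <= 0:
        raise ValueError("grid has no positive density")
    level = _threshold_level(data, threshold, absolute)
    occupied = np.where((data >= level).any(axis=(1, 2)))[0]
    if len(occupied) == 0:
        raise ValueError("no density above threshold")
    return float((occupied[-1] - occupied[0] + 1) * grid.voxel_size)


def gate_state(grid: VoxelGrid, z_range: tuple, threshold: float = 0.5,
               absolute: bool = False, lumen_radius: float | None = None):
    """Open/closed state of the axial channel across ``z_range`` (Angstrom).

    The region is *open* iff one background (below-threshold) connected
    component within a cylindrical neighborhood of the long axis spans the
    whole z range.  Also returns the per-section lumen diameter profile
    (``0`` where the section is closed on-axis).
    """
    data = grid.data
    vs = grid.voxel_size
    n = data.shape[0]
    c = n // 2
    lo = int(round(z_range[0] / vs + c))
    hi = int(round(z_range[1] / vs + c))
    lo, hi = max(min(lo, hi), 0), min(max(lo, hi), n - 1)
    level = _threshold_level(data, threshold, absolute)

    yy, xx = np.indices((n, n))
    r = np.hypot(yy - c, xx - c) * vs
    radius = lumen_radius if lumen_radius is not None else n * vs / 4.0
    near_axis = r <= radius

    region = data[lo:hi + 1]
    background = (region < level) & near_axis[None]
    labels, _ = ndimage.label(background)
    open_state = False
    axis_label_bottom = labels[0, c, c]
    if axis_label_bottom > 0 and labels[-1, c, c] == axis_label_bottom:
        open_state = True

    profile = []
    for iz in range(lo, hi + 1):
        section_bg = (data[iz] < level) & near_axis
        lum = 0.0
        if section_bg[c, c]:
            lab2, _ = ndimage.label(section_bg)
            comp = lab2 == lab2[c, c]
            lum = 2.0 * np.sqrt(comp.sum() * vs * vs / np.pi)
        profile.append(((iz - c) * vs, lum))
    return {"state": "open" if open_state else "closed",
            "lumen_profile": profile, "threshold": threshold,
            "absolute": absolute}
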