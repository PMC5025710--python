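"""Grid/image data model, MRC and PDB I/O, Fourier filters, resolution arithmetic.

Conventions used throughout the package:

* 3D arrays are indexed ``(z, y, x)``; ``z`` is the particle long axis.
* Physical coordinates are in Angstrom, measured relative to the *box
  center voxel* ``n // 2`` (the FFT center for even boxes), as an
  ``(x, y, z)`` triple.
* All maps are real-valued; MRC output is mode 2 (float32).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import mrcfile
import numpy as np

__all__ = [
    "VoxelGrid",
    "Image2D",
    "AtomicModel",
    "read_mrc",
    "write_mrc",
    "read_structure",
    "resolution_at_nyquist_fraction",
    "low_pass_filter",
    "flip_hand",
    "ATOMIC_WEIGHTS",
]


class MapFormatError(ValueError):
    """Raised for malformed or unsupported map files."""


#: Standard atomic weights (u) for the elements that occur in protein /
#: nucleotide structures; anything else falls back on the first character.
ATOMIC_WEIGHTS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904, "W": 183.84,
}


def _check_finite(data: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class VoxelGrid:
    """A real-valued cubic 3D density map with isotropic voxel size.

    Parameters
    ----------
    data
        Density array indexed ``(z, y, x)``.
    voxel_size
        Edge length of one voxel in Angstrom.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in Angstrom (MRC origin).
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid data must be 3-dimensional")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        _check_finite(self.data, "VoxelGrid data")

    @property
    def shape(self):
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        nz, ny, nx = self.data.shape
        return nz == ny == nx

    def require_cubic(self) -> "VoxelGrid":
        if not self.is_cubic:
            raise ValueError(f"operation requires a cubic box, got {self.data.shape}")
        return self

    def pad_to_cube(self) -> "VoxelGrid":
        """Symmetrically zero-pad a non-cubic grid to its largest dimension."""
        n = max(self.data.shape)
        pads = []
        for s in self.data.shape:
            before = (n - s) // 2
            pads.append((before, n - s - before))
        return VoxelGrid(np.pad(self.data, pads), self.voxel_size, self.origin,
                         dict(self.meta))

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.voxel_size, self.origin,
                         dict(self.meta))


@dataclass
class Image2D:
    """A real-valued square 2D image (class average or projection)."""

    data: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Image2D data must be 2-dimensional")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        _check_finite(self.data, "Image2D data")

    @property
    def shape(self):
        return self.data.shape

    def copy(self) -> "Image2D":
        return Image2D(self.data.copy(), self.pixel_size, dict(self.meta))


@dataclass
class AtomicModel:
    """Atom records (element, weight, Cartesian coordinates in Angstrom).

    ``coords`` is an ``(n, 3)`` array of ``(x, y, z)`` positions.  Chain and
    residue identifiers are retained so sub-selections (e.g. one chain, a
    residue range) can be taken after reading.
    """

    elements: np.ndarray
    weights: np.ndarray
    coords: np.ndarray
    chain_ids: np.ndarray | None = None
    res_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.elements = np.asarray(self.elements)
        if len(self.coords) == 0:
            raise ValueError("AtomicModel must contain at least one atom")
        if self.coords.shape != (len(self.weights), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        _check_finite(self.coords, "coordinates")
        if np.any(self.weights <= 0):
            raise ValueError("atomic weights must be positive")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def center_of_mass(self) -> np.ndarray:
        w = self.weights
        return (self.coords * w[:, None]).sum(axis=0) / w.sum()

    def _subset(self, mask: np.ndarray) -> "AtomicModel":
        if not mask.any():
            raise ValueError("selection is empty")
        return AtomicModel(
            self.elements[mask], self.weights[mask], self.coords[mask],
            None if self.chain_ids is None else self.chain_ids[mask],
            None if self.res_ids is None else self.res_ids[mask],
        )

    def select(self, chain: str | None = None,
               residue_range: tuple | None = None) -> "AtomicModel":
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            if self.chain_ids is None:
                raise ValueError("model has no chain identifiers")
            mask &= self.chain_ids == chain
        if residue_range is not None:
            if self.res_ids is None:
                raise ValueError("model has no residue identifiers")
            lo, hi = residue_range
            mask &= (self.res_ids >= lo) & (self.res_ids <= hi)
        return self._subset(mask)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomicModel":
        """Return a copy with ``coords -> R @ coords + t`` (about the origin)."""
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return AtomicModel(self.elements, self.weights, coords,
                           self.chain_ids, self.res_ids)

    def centered(self) -> "AtomicModel":
        """Shift the weighted center of mass to the origin."""
        return self.transformed(translation=-self.center_of_mass)


# ---------------------------------------------------------------------------
# MRC I/O
# ---------------------------------------------------------------------------

def read_mrc(path, anisotropy_tolerance: float = 1e-3,
             pad_non_cubic: bool = False):
    """Read an MRC2014 file into a :class:`VoxelGrid` or :class:`Image2D`.

    Files with a single section (``nz == 1``) are returned as
    :class:`Image2D`.  Anisotropic voxel sizes are rejected unless within
    ``anisotropy_tolerance`` (relative).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with mrcfile.open(path, permissive=False) as mrc:
            data = np.asarray(mrc.data, dtype=np.float64)
            vs = mrc.voxel_size
            sizes = np.array([float(vs.x), float(vs.y), float(vs.z)])
            origin = (float(mrc.header.origin.x), float(mrc.header.origin.y),
                      float(mrc.header.origin.z))
    except ValueError as exc:
        raise MapFormatError(f"malformed MRC file {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MapFormatError(f"unsupported dimensionality {data.ndim} in {path}")

    nz, ny, nx = data.shape
    if nz == 1:
        if nx != ny:
            raise MapFormatError(f"2D image must be square, got {ny}x{nx}")
        rel = abs(sizes[0] - sizes[1]) / max(sizes[0], 1e-30)
        if rel > anisotropy_tolerance:
            raise MapFormatError(f"anisotropic pixel size {sizes[:2]}")
        return Image2D(data[0], float(sizes[:2].mean()))

    rel = (sizes.max() - sizes.min()) / max(sizes.max(), 1e-30)
    if rel > anisotropy_tolerance:
        raise MapFormatError(f"anisotropic voxel size {sizes}")
    grid = VoxelGrid(data, float(sizes.mean()), origin)
    if not grid.is_cubic:
        if pad_non_cubic:
            grid = grid.pad_to_cube()
        else:
            raise MapFormatError(
                f"non-cubic box {data.shape}; pass pad_non_cubic=True to pad")
    return grid


def write_mrc(obj, path) -> None:
    """Write a :class:`VoxelGrid` or :class:`Image2D` as MRC2014 mode 2."""
    if isinstance(obj, VoxelGrid):
        data = obj.data
        vsize = obj.voxel_size
        origin = obj.origin
    elif isinstance(obj, Image2D):
        data = obj.data[None]
        vsize = obj.pixel_size
        origin = (0.0, 0.0, 0.0)
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    _check_finite(data, "map data")
    with mrcfile.new(path, overwrite=True) as mrc:
        mrc.set_data(np.asarray(data, dtype=np.float32))
        mrc.voxel_size = vsize
        mrc.header.origin.x = origin[0]
        mrc.header.origin.y = origin[1]
        mrc.header.origin.z = origin[2]
        mrc.update_header_stats()


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def _weight_for_element(element: str) -> float:
    el = element.strip().upper()
    if el in ATOMIC_WEIGHTS:
        return ATOMIC_WEIGHTS[el]
    if el and el[0] in ATOMIC_WEIGHTS:
        warnings.warn(
            f"unknown element {element!r}; using weight of {el[0]!r}",
            stacklevel=3)
        return ATOMIC_WEIGHTS[el[0]]
    raise ValueError(f"cannot assign a weight to element {element!r}")


def read_structure(path, chain: str | None = None,
                   residue_range: tuple | None = None,
                   drop_hydrogens: bool = True) -> AtomicModel:
    """Read atoms from a PDB or mmCIF file into an :class:`AtomicModel`.

    Parameters
    ----------
    chain
        Keep only the given chain identifier.
    residue_range
        ``(first, last)`` residue numbers to keep, inclusive.
    drop_hydrogens
        Discard H/D atoms (default), matching common density-rendering use.
    """
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        from biotite.structure.io.pdbx import CIFFile, get_structure
        cif = CIFFile.read(path)
        atoms = get_structure(cif, model=1)
    else:
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(path)
        atoms = pdb.get_structure(model=1)

    elements = np.array([e.upper() for e in atoms.element])
    keep = np.ones(len(elements), dtype=bool)
    if drop_hydrogens:
        keep &= ~np.isin(elements, ("H", "D"))
    if not keep.any():
        raise ValueError("selection is empty after hydrogen removal")
    weights = np.array([_weight_for_element(e) for e in elements[keep]])
    model = AtomicModel(
        elements[keep], weights, np.asarray(atoms.coord)[keep],
        chain_ids=np.asarray(atoms.chain_id)[keep],
        res_ids=np.asarray(atoms.res_id)[keep],
    )
    if chain is not None or residue_range is not None:
        model = model.select(chain=chain, residue_range=residue_range)
    return model


# ---------------------------------------------------------------------------
# Resolution arithmetic and Fourier filters
# ---------------------------------------------------------------------------

def resolution_at_nyquist_fraction(pixel_size: float, fraction: float) -> float:
    """Real-space resolution (Angstrom) at ``fraction`` of the Nyquist frequency.

    Nyquist is ``1 / (2 * pixel_size)``; the resolution at a fraction ``f``
    of it is ``2 * pixel_size / f``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return 2.0 * pixel_size / fraction


def _radial_freq_pixels(shape) -> np.ndarray:
    """Radius (in Fourier pixels) of every unshifted FFT sample."""
    axes = [np.fft.fftfreq(n) * n for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g * g for g in grids))


def _lowpass_mask(shape, voxel_size: float, cutoff: float,
                  edge_width: float) -> np.ndarray:
    n = shape[0]
    r = _radial_freq_pixels(shape)
    r_cut = n * voxel_size / cutoff  # cutoff radius in Fourier pixels
    mask = np.ones(shape)
    if edge_width > 0:
        edge = (r > r_cut) & (r <= r_cut + edge_width)
        mask[edge] = 0.5 * (1.0 + np.cos(np.pi * (r[edge] - r_cut) / edge_width))
        mask[r > r_cut + edge_width] = 0.0
    else:
        mask[r > r_cut] = 0.0
    return mask


def low_pass_filter(obj, cutoff: float, edge_width: float = 3.0):
    """Low-pass filter a grid or image with a raised-cosine Fourier edge.

    Amplitudes at radii beyond ``1/cutoff`` are attenuated by a cosine ramp
    of ``edge_width`` Fourier pixels; DC (and hence the mean) is untouched.
    """
    if isinstance(obj, VoxelGrid):
        spacing, data = obj.voxel_size, obj.data
    elif isinstance(obj, Image2D):
        spacing, data = obj.pixel_size, obj.data
    else:
        raise TypeError(f"cannot filter object of type {type(obj)!r}")
    if cutoff < 2.0 * spacing:
        raise ValueError(
            f"cutoff {cutoff} below Nyquist limit {2 * spacing} A")
    mask = _lowpass_mask(data.shape, spacing, cutoff, edge_width)
    filtered = np.fft.ifftn(np.fft.fftn(data) * mask).real
    if isinstance(obj, VoxelGrid):
        return VoxelGrid(filtered, spacing, obj.origin, dict(obj.meta))
    return Image2D(filtered, spacing, dict(obj.meta))


def flip_hand(grid: VoxelGrid) -> VoxelGrid:
    """Mirror the grid along x, flipping the handedness of the map.

    The mirror plane passes through the center voxel ``n // 2`` (the
    geometric reference used everywhere else), so centered achiral maps are
    unchanged and applying the flip twice is the identity.
    """
    flipped = np.roll(grid.data[:, :, ::-1], 1, axis=2)
    return VoxelGrid(np.ascontiguousarray(flipped),
                     grid.voxel_size, grid.origin, dict(grid.meta))
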