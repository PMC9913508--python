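"""Grid geometry, binary masks, scalar volumes and volumetric file I/O.

All world coordinates are RAS millimeters.  Voxel indices are 0-based and
node-centered: index ``(0, 0, 0)`` maps exactly to ``origin``, and the grid
samples are voxel *centers*.  The affine relation is::

    world = origin + direction @ (index * spacing)

with ``direction`` an orthonormal 3x3 matrix (columns are the world
directions of the index axes).  NIfTI files are read/written through
nibabel (whose affines are RAS by construction); NRRD files go through
SimpleITK, whose LPS convention is converted to RAS on read and back on
write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridGeometry",
    "BinaryMask",
    "ScalarVolume",
    "volume_cm3",
    "resample_mask",
    "resample_scalar",
    "mask_and",
    "mask_or",
    "mask_diff",
    "read_mask",
    "read_scalar",
    "write_volume",
]

_ORTHO_TOL = 1e-6
# diag(-1,-1,1): RAS <-> LPS flips the sign of the first two world axes
_RAS2LPS = np.diag([-1.0, -1.0, 1.0])


@dataclass(frozen=True, eq=False)
class GridGeometry:
    """Axis-aligned-in-index-space sampling lattice in world (RAS) mm."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float).reshape(3))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float).reshape(3, 3))
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three counts >= 1, got {self.shape}")
        d = self.direction
        if not np.allclose(d.T @ d, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix columns must be orthonormal")

    # -- affine ----------------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """4x4 index-to-world homogeneous transform."""
        a = np.eye(4)
        a[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """Map (continuous) voxel indices to world mm.  Accepts (3,) or (n, 3)."""
        idx = np.asarray(index, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_index(self, point) -> np.ndarray:
        """Inverse of :meth:`index_to_world`; out-of-bounds indices are returned as-is."""
        p = np.asarray(point, dtype=float)
        return (p - self.origin) @ self.direction / self.spacing

    def center_grid(self, i_slice=None, j_slice=None, k_slice=None):
        """World coordinates of voxel centers on a (sub)grid.

        Returns three broadcastable arrays ``(X, Y, Z)`` of the world x/y/z
        components over the requested index ranges (full grid by default).
        The computation is separable per index axis, so a subgrid produces
        bit-identical coordinates to slicing the full grid.
        """
        slices = []
        for sl, n in zip((i_slice, j_slice, k_slice), self.shape):
            slices.append(np.arange(n, dtype=float) if sl is None else np.arange(sl.start, sl.stop, dtype=float))
        ia, ja, ka = slices
        out = []
        for w in range(3):
            comp = (
                self.origin[w]
                + (ia * self.spacing[0] * self.direction[w, 0])[:, None, None]
                + (ja * self.spacing[1] * self.direction[w, 1])[None, :, None]
                + (ka * self.spacing[2] * self.direction[w, 2])[None, None, :]
            )
            out.append(comp)
        return tuple(out)

    def same_lattice(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def __eq__(self, other):
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return self.same_lattice(other, tol=0.0)


@dataclass(eq=False)
class BinaryMask:
    """A binary segmentation (tumor, cerebrum, residual, cavity...) on a grid."""

    geometry: GridGeometry
    voxels: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask voxels must be 0/1")
            v = v.astype(bool)
        if v.shape != self.geometry.shape:
            raise ValueError(f"voxel array shape {v.shape} != geometry shape {self.geometry.shape}")
        self.voxels = v

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def volume_cm3(self) -> float:
        return volume_cm3(self)

    def __eq__(self, other):
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.geometry == other.geometry and np.array_equal(self.voxels, other.voxels)


@dataclass
class ScalarVolume:
    """A real-valued volume (e.g. the MRI background used for overlays)."""

    geometry: GridGeometry
    voxels: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=float)
        if v.shape != self.geometry.shape:
            raise ValueError(f"voxel array shape {v.shape} != geometry shape {self.geometry.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("scalar volume values must be finite")
        self.voxels = v


def volume_cm3(mask: BinaryMask) -> float:
    """Volume of the foreground in cm^3 (voxel count x voxel volume / 1000)."""
    return mask.count * mask.geometry.voxel_volume_mm3 / 1000.0


def _target_source_indices(target: GridGeometry, source: GridGeometry):
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), np.arange(target.shape[2]), indexing="ij"
    )
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = target.index_to_world(pts)
    cont = source.world_to_index(world)
    idx = np.rint(cont).astype(np.int64)
    inb = np.all((idx >= 0) & (idx < np.array(source.shape)), axis=1)
    return idx, inb


def resample_mask(mask: BinaryMask, target: GridGeometry) -> BinaryMask:
    """Nearest-neighbor resampling onto ``target``.

    Each target voxel takes the value of the source voxel whose center is
    nearest (in world space) to the target voxel center; target centers
    farther than half a voxel outside the source lattice become 0.  Binary
    semantics are preserved exactly — masks are never interpolated.
    """
    if mask.geometry.same_lattice(target):
        return BinaryMask(target, mask.voxels.copy())
    idx, inb = _target_source_indices(target, mask.geometry)
    out = np.zeros(len(idx), dtype=bool)
    sel = idx[inb]
    out[inb] = mask.voxels[sel[:, 0], sel[:, 1], sel[:, 2]]
    return BinaryMask(target, out.reshape(target.shape))


def resample_scalar(vol: ScalarVolume, target: GridGeometry, fill: float = 0.0) -> ScalarVolume:
    """Trilinear resampling of a scalar volume onto ``target`` (rendering only)."""
    from scipy.ndimage import map_coordinates

    if vol.geometry.same_lattice(target):
        return ScalarVolume(target, vol.voxels.copy())
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), np.arange(target.shape[2]), indexing="ij"
    )
    pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    cont = vol.geometry.world_to_index(target.index_to_world(pts))
    vals = map_coordinates(vol.voxels, cont.T, order=1, mode="constant", cval=fill)
    return ScalarVolume(target, vals.reshape(target.shape))


def _check_same_geometry(a: BinaryMask, b: BinaryMask, op: str):
    if not a.geometry.same_lattice(b.geometry):
        raise ValueError(
            f"mask {op}: geometries differ (shapes {a.geometry.shape} vs {b.geometry.shape}); "
            "resample onto a common grid first"
        )


def mask_and(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_geometry(a, b, "intersection")
    return BinaryMask(a.geometry, a.voxels & b.voxels)


def mask_or(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_geometry(a, b, "union")
    return BinaryMask(a.geometry, a.voxels | b.voxels)


def mask_diff(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    _check_same_geometry(a, b, "difference")
    return BinaryMask(a.geometry, a.voxels & ~b.voxels)


# ---------------------------------------------------------------------------
# File I/O: NIfTI via nibabel (native RAS), NRRD via SimpleITK (LPS <-> RAS)
# ---------------------------------------------------------------------------

def _geometry_from_affine(affine: np.ndarray, shape) -> GridGeometry:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("degenerate affine (zero-length axis)")
    direction = m / spacing[np.newaxis, :]
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise ValueError("volume has a non-orthonormal direction matrix (sheared affine)")
    return GridGeometry(origin=affine[:3, 3], spacing=spacing, shape=shape, direction=direction)


def _read_raw(path: str):
    ext = _extension(path)
    if ext in (".nii", ".nii.gz"):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        geom = _geometry_from_affine(img.affine, data.shape)
        return geom, data
    if ext == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        lps_dir = np.asarray(img.GetDirection()).reshape(3, 3)
        geom = GridGeometry(
            origin=_RAS2LPS @ np.asarray(img.GetOrigin()),
            spacing=np.asarray(img.GetSpacing()),
            shape=data.shape,
            direction=_RAS2LPS @ lps_dir,
        )
        return geom, data
    raise ValueError(f"unknown volume extension on {path!r} (expected .nii, .nii.gz or .nrrd)")


def _extension(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


def read_mask(path: str) -> BinaryMask:
    """Read a binary segmentation from NIfTI or NRRD."""
    geom, data = _read_raw(path)
    return BinaryMask(geom, data)


def read_scalar(path: str) -> ScalarVolume:
    """Read a scalar volume from NIfTI or NRRD."""
    geom, data = _read_raw(path)
    return ScalarVolume(geom, np.nan_to_num(np.asarray(data, dtype=float), nan=0.0))


def read_scalar_raw(path: str):
    """Read a scalar volume keeping NaNs (used for map checkpoints)."""
    geom, data = _read_raw(path)
    return geom, np.asarray(data, dtype=float)


def write_volume(path: str, vol) -> None:
    """Write a BinaryMask (uint8) or ScalarVolume / raw array (float64) to NIfTI or NRRD."""
    if isinstance(vol, BinaryMask):
        data = vol.voxels.astype(np.uint8)
        geom = vol.geometry
    elif isinstance(vol, ScalarVolume):
        data = np.asarray(vol.voxels, dtype=np.float64)
        geom = vol.geometry
    else:
        geom, arr = vol  # (GridGeometry, ndarray) pair, e.g. SDF checkpoints
        data = np.asarray(arr, dtype=np.float64)
    ext = _extension(path)
    if ext in (".nii", ".nii.gz"):
        import nibabel as nib

        img = nib.Nifti1Image(data, geom.affine)
        nib.save(img, path)
    elif ext == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
        img.SetSpacing(tuple(geom.spacing))
        img.SetOrigin(tuple(_RAS2LPS @ geom.origin))
        img.SetDirection(tuple((_RAS2LPS @ geom.direction).ravel()))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unknown volume extension on {path!r} (expected .nii, .nii.gz or .nrrd)")
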