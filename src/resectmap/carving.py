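"""The carving engine: a truncated signed-distance-field resection map.

The map covers a region-of-interest box enclosing the tumor and adjacent
areas at sub-millimeter resolution.  Each voxel stores the signed distance
(mm) to the surface of the volume swept so far by tracked tool tips:
negative inside the carved cavity, positive outside, clamped to a narrow
band ``[-band_mm, +band_mm]``.  Carving a tool-tip sample at position ``p``
with effective tool radius ``r`` applies, at every voxel center ``x``::

    sdf(x) <- min(sdf(x), max(|x - p| - r, -band))

so the update is a pointwise min and the field only ever decreases
(resection only removes tissue).  Consecutive samples that are close in
time and space are linked into capsules (distance to the segment between
them), which fills inter-sample motion so a 15-30 Hz stream carves a
connected channel; samples separated by a line-of-sight dropout are carved
as isolated spheres to avoid fictitious tunnels.  Each voxel also records
the earliest timestamp at which it became interior (``first_carved_s``),
enabling time-coded replay of the resection sequence.

The effective tool radius is the single most consequential parameter that
is not dictated by the input data: it models the tissue removed around the
tracked tip (bipolar forceps, CUSA, pointer).  The default of 1.5 mm
approximates those tips; see :class:`CarveConfig`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .tracking import TrackingLog
from .volume import (BinaryMask, GridGeometry, ScalarVolume, resample_mask,
                     resample_scalar, write_volume)

__all__ = [
    "CarveConfig",
    "ResectionMap",
    "init_map",
    "extract_surface",
    "time_colored_surface",
    "overlay_slice",
    "export_mesh",
    "load_time_colored_ply",
    "save_overlay_png",
    "save_map",
    "load_map",
    "auto_roi",
]


@dataclass(frozen=True)
class CarveConfig:
    """Parameters of the carving engine.

    tool_radius_mm
        Effective carving radius around the tracked tip, mm.  Not a tracked
        quantity — it stands in for the aperture of the instrument
        (bipolar/CUSA/pointer tips are all in the 1-2 mm range).  Default 1.5.
    grid_spacing_mm
        Map voxel edge length, mm.  Sub-millimeter by default (0.5).
    band_mm
        Truncation distance of the signed distance field, mm.  Must be
        >= tool_radius_mm; 3.0 (2x the radius) keeps the narrow band cheap
        while supporting smooth surface extraction.
    link_max_gap_s, link_max_jump_mm
        Consecutive samples closer than both thresholds are carved as a
        capsule; anything farther apart (dropout re-acquisition, instrument
        exchange) is carved as an isolated sphere.
    """

    tool_radius_mm: float = 1.5
    grid_spacing_mm: float = 0.5
    band_mm: float = 3.0
    link_max_gap_s: float = 0.5
    link_max_jump_mm: float = 10.0

    def __post_init__(self):
        if self.tool_radius_mm <= 0:
            raise ValueError("tool_radius_mm must be > 0")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid_spacing_mm must be > 0")
        if self.band_mm < self.tool_radius_mm:
            raise ValueError("band_mm must be >= tool_radius_mm")
        if self.link_max_gap_s <= 0 or self.link_max_jump_mm <= 0:
            raise ValueError("link thresholds must be > 0")


class ResectionMap:
    """Truncated SDF resection map with per-voxel earliest-carve timestamps."""

    def __init__(self, geometry: GridGeometry, config: CarveConfig,
                 sdf: Optional[np.ndarray] = None, first_carved_s: Optional[np.ndarray] = None):
        self.geometry = geometry
        self.config = config
        self.sdf = np.full(geometry.shape, config.band_mm, dtype=float) if sdf is None else np.asarray(sdf, float)
        if self.sdf.shape != geometry.shape:
            raise ValueError("sdf shape does not match geometry")
        self.first_carved_s = (
            np.full(geometry.shape, np.nan, dtype=float) if first_carved_s is None else np.asarray(first_carved_s, float)
        )
        # streaming state: last ingested sample, so chunked ingestion links
        # capsules across calls exactly like batch ingestion
        self._last: Optional[Tuple[float, np.ndarray]] = None

    # -- carve primitives ------------------------------------------------
    def _subbox(self, lo_world: np.ndarray, hi_world: np.ndarray):
        """Index slices of the voxels whose centers may fall inside a world box."""
        corners = np.array([[lo_world[i] if b & (1 << i) == 0 else hi_world[i] for i in range(3)]
                            for b in range(8)])
        idx = self.geometry.world_to_index(corners)
        lo = np.maximum(np.floor(idx.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int), np.array(self.geometry.shape) - 1)
        if np.any(lo > hi):
            return None
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))

    def _apply_distance(self, dist: np.ndarray, slices, timestamp: float) -> None:
        cfg = self.config
        new = np.maximum(dist - cfg.tool_radius_mm, -cfg.band_mm)
        sub = self.sdf[slices]
        upd = np.minimum(sub, new)
        newly = (upd < 0) & (sub >= 0)
        if newly.any():
            fc = self.first_carved_s[slices]
            fc[newly] = timestamp
        self.sdf[slices] = upd

    def carve_sample(self, position, timestamp: float) -> None:
        """Carve a sphere of the tool radius at one tool-tip position."""
        p = np.asarray(position, dtype=float).reshape(3)
        pad = self.config.band_mm + self.config.tool_radius_mm
        slices = self._subbox(p - pad, p + pad)
        if slices is None:
            return
        X, Y, Z = self.geometry.center_grid(*slices)
        dist = np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2)
        self._apply_distance(dist, slices, timestamp)

    def carve_capsule(self, p_prev, p_next, timestamp: float) -> None:
        """Carve the capsule swept between two consecutive samples.

        Timestamp attribution uses the later sample's time; voxels already
        carved keep their earlier timestamp (first-carve wins).
        """
        p0 = np.asarray(p_prev, dtype=float).reshape(3)
        p1 = np.asarray(p_next, dtype=float).reshape(3)
        v = p1 - p0
        denom = float(v @ v)
        if denom == 0.0:
            self.carve_sample(p1, timestamp)
            return
        pad = self.config.band_mm + self.config.tool_radius_mm
        slices = self._subbox(np.minimum(p0, p1) - pad, np.maximum(p0, p1) + pad)
        if slices is None:
            return
        X, Y, Z = self.geometry.center_grid(*slices)
        dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
        tt = np.clip((dx * v[0] + dy * v[1] + dz * v[2]) / denom, 0.0, 1.0)
        dist = np.sqrt((dx - tt * v[0]) ** 2 + (dy - tt * v[1]) ** 2 + (dz - tt * v[2]) ** 2)
        self._apply_distance(dist, slices, timestamp)

    # -- streaming -------------------------------------------------------
    def ingest(self, log: TrackingLog) -> "ResectionMap":
        """Process a time-ordered log, capsule-linking within the configured
        thresholds.  Streaming in chunks is bit-identical to batch ingestion
        (the last sample is retained across calls).  Returns self.
        """
        if len(log) and np.any(np.diff(log.t) < 0):
            raise ValueError("log timestamps must be non-decreasing")
        cfg = self.config
        for i in range(len(log)):
            t = float(log.t[i])
            p = log.xyz[i]
            if self._last is not None:
                t0, p0 = self._last
                if (t - t0) <= cfg.link_max_gap_s and float(np.linalg.norm(p - p0)) <= cfg.link_max_jump_mm:
                    self.carve_capsule(p0, p, t)
                else:
                    self.carve_sample(p, t)
            else:
                self.carve_sample(p, t)
            self._last = (t, p.copy())
        return self

    # -- queries ---------------------------------------------------------
    def binarize(self) -> BinaryMask:
        """The tracked resection cavity: strictly negative SDF (the zero
        level set is the cavity surface, not cavity content)."""
        return BinaryMask(self.geometry, self.sdf < 0)

    def carved_volume_cm3(self) -> float:
        return self.binarize().volume_cm3()

    def copy(self) -> "ResectionMap":
        m = ResectionMap(self.geometry, self.config, self.sdf.copy(), self.first_carved_s.copy())
        m._last = None if self._last is None else (self._last[0], self._last[1].copy())
        return m


def init_map(box_min, box_max, config: CarveConfig,
             direction: Optional[np.ndarray] = None) -> ResectionMap:
    """Create an empty map whose grid covers the world-space ROI box.

    The grid includes voxel centers on both faces of the box (a 10 mm box
    at 0.5 mm spacing yields 21 samples per axis) and extends past the box
    when the extent is not a multiple of the spacing.
    """
    lo = np.asarray(box_min, dtype=float).reshape(3)
    hi = np.asarray(box_max, dtype=float).reshape(3)
    if np.any(hi <= lo):
        raise ValueError(f"degenerate ROI box: min {lo}, max {hi}")
    h = config.grid_spacing_mm
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / h - 1e-9)) + 1 for a in range(3))
    geom = GridGeometry(origin=lo, spacing=(h, h, h), shape=shape,
                        direction=np.eye(3) if direction is None else direction)
    return ResectionMap(geom, config)


def auto_roi(tumor: BinaryMask, margin_mm: float = 10.0,
             clip_to: Optional[BinaryMask] = None) -> Tuple[np.ndarray, np.ndarray]:
    """ROI box enclosing the tumor plus a margin (optionally clipped to the brain).

    Returns (box_min, box_max) in world mm.  Assumes an axis-aligned
    (identity-direction) tumor grid for the bounding box computation.
    """
    if tumor.count == 0:
        raise ValueError("cannot derive an ROI from an empty tumor mask")
    idx = np.array(np.nonzero(tumor.voxels))
    lo = tumor.geometry.index_to_world(idx.min(axis=1)) - margin_mm
    hi = tumor.geometry.index_to_world(idx.max(axis=1)) + margin_mm
    if clip_to is not None and clip_to.count:
        bidx = np.array(np.nonzero(clip_to.voxels))
        blo = clip_to.geometry.index_to_world(bidx.min(axis=1))
        bhi = clip_to.geometry.index_to_world(bidx.max(axis=1))
        lo, hi = np.maximum(lo, blo), np.minimum(hi, bhi)
    return lo, hi


# ---------------------------------------------------------------------------
# Surfaces and overlays
# ---------------------------------------------------------------------------

def extract_surface(rmap: ResectionMap):
    """Marching-cubes triangle mesh of the SDF zero level set (world mm)."""
    import trimesh
    from skimage.measure import marching_cubes

    if not np.any(rmap.sdf < 0):
        raise ValueError("nothing carved: the resection map has no interior voxels")
    verts, faces, _, _ = marching_cubes(rmap.sdf, level=0.0, spacing=tuple(rmap.geometry.spacing))
    world = verts @ rmap.geometry.direction.T + rmap.geometry.origin
    return trimesh.Trimesh(vertices=world, faces=faces, process=False)


def time_colored_surface(rmap: ResectionMap):
    """Surface mesh with per-vertex scalar = earliest carve time (s) of the
    nearest carved voxel, for color-coded replay of the resection sequence."""
    from scipy.ndimage import distance_transform_edt

    mesh = extract_surface(rmap)
    carved = rmap.sdf < 0
    _, nearest = distance_transform_edt(~carved, sampling=rmap.geometry.spacing, return_indices=True)
    cont = rmap.geometry.world_to_index(mesh.vertices)
    vi = np.clip(np.rint(cont).astype(int), 0, np.array(rmap.geometry.shape) - 1)
    ni = nearest[:, vi[:, 0], vi[:, 1], vi[:, 2]]
    times = rmap.first_carved_s[ni[0], ni[1], ni[2]]
    mesh.vertex_attributes["time_s"] = times
    return mesh


def export_mesh(mesh, path: str) -> None:
    """Write PLY (ASCII, with any per-vertex ``time_s`` property) or STL.

    Vertices are stored as float32 (the PLY/STL norm), so exported
    coordinates round-trip exactly at that precision.
    """
    p = str(path)
    mesh = mesh.copy(include_cache=False)
    mesh.vertices = mesh.vertices.astype(np.float32)
    if p.lower().endswith(".ply"):
        from trimesh.exchange.ply import export_ply

        data = export_ply(mesh, encoding="ascii", include_attributes=True)
        with open(p, "wb") as fh:
            fh.write(data)
    elif p.lower().endswith(".stl"):
        mesh.export(p)
    else:
        raise ValueError(f"unknown mesh extension on {path!r} (expected .ply or .stl)")


def load_time_colored_ply(path: str):
    """Load a PLY mesh, recovering the per-vertex ``time_s`` property if present."""
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    if isinstance(raw, dict) and "time_s" in raw:
        mesh.vertex_attributes["time_s"] = np.asarray(raw["time_s"], dtype=float).reshape(-1)
    return mesh


def overlay_slice(rmap: ResectionMap, background: ScalarVolume, axis: int, index: int,
                  tumor: Optional[BinaryMask] = None,
                  residual: Optional[BinaryMask] = None) -> np.ndarray:
    """2D RGB overlay of the cavity (and optional tumor/residual contours)
    on an orthogonal background slice.  Pure rendering: returns a uint8
    H x W x 3 array, no analysis side effects.

    axis 0/1/2 selects the sagittal/coronal/axial index axis of the map grid.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    n = rmap.geometry.shape[axis]
    if not (0 <= index < n):
        raise ValueError(f"slice index {index} out of range [0, {n})")
    bg = resample_scalar(background, rmap.geometry) if not background.geometry.same_lattice(rmap.geometry) else background
    bg_sl = np.take(bg.voxels, index, axis=axis)
    lo, hi = np.percentile(bg_sl, [1, 99]) if bg_sl.size else (0.0, 1.0)
    gray = np.zeros_like(bg_sl) if hi <= lo else np.clip((bg_sl - lo) / (hi - lo), 0, 1)
    rgb = np.repeat((gray[..., None] * 255).astype(np.uint8), 3, axis=2)

    cav = np.take(rmap.sdf, index, axis=axis) < 0
    rgb[cav] = (0.5 * rgb[cav] + 0.5 * np.array([255, 64, 160])).astype(np.uint8)  # cavity fill, pink

    def _contour(mask: BinaryMask, color):
        from scipy.ndimage import binary_erosion

        if not mask.geometry.same_lattice(rmap.geometry):
            mask = resample_mask(mask, rmap.geometry)
        sl = np.take(mask.voxels, index, axis=axis)
        edge = sl & ~binary_erosion(sl)
        rgb[edge] = color

    if tumor is not None:
        _contour(tumor, np.array([0, 200, 0], dtype=np.uint8))
    if residual is not None:
        _contour(residual, np.array([240, 220, 0], dtype=np.uint8))
    return rgb


def save_overlay_png(path: str, rgb: np.ndarray) -> None:
    """Write an overlay slice (H x W x 3 uint8, as from overlay_slice) to PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_map(rmap: ResectionMap, sdf_path: str, first_carved_path: str) -> None:
    """Checkpoint the map as two NRRD volumes (NaN = never carved)."""
    write_volume(sdf_path, (rmap.geometry, rmap.sdf))
    write_volume(first_carved_path, (rmap.geometry, rmap.first_carved_s))


def load_map(sdf_path: str, first_carved_path: str, config: CarveConfig) -> ResectionMap:
    from .volume import read_scalar_raw

    geom, sdf = read_scalar_raw(sdf_path)
    geom2, fc = read_scalar_raw(first_carved_path)
    if not geom.same_lattice(geom2):
        raise ValueError("sdf and first_carved checkpoints are on different grids")
    return ResectionMap(geom, config, sdf, fc)
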