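"""Volumetric image I/O and manual-trace rasterization.

The module defines the two carrier types used throughout the package —
:class:`VoxelGrid` for scalar MRI/phantom intensities and :class:`BinaryMask`
for per-structure segmentations — plus readers/writers for NIfTI files and
DICOM series, and the rasterizer that turns per-slice manual trace polygons
into binary mask volumes.

Geometry convention
-------------------
All physical coordinates are millimetres.  Voxel ``(i, j, k)`` covers the
half-open cube ``[i*s, (i+1)*s)`` (plus the grid origin) and its *center*
sits at ``origin + (i + 0.5) * spacing``.  Indices are 0-based.  Volumes are
stored sagittally: slices are taken along axis 0, so a trace polygon for
slice ``i`` lives in the (axis-1, axis-2) plane.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "TracePolygonSet",
    "TraceSlice",
    "read_volume",
    "write_volume",
    "read_traces",
    "write_traces",
    "traces_to_mask",
    "voxel_centers_1d",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar image with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities (arbitrary units).
    spacing : tuple of 3 floats
        Voxel edge length in mm along each axis.
    origin : tuple of 3 floats
        Physical position (mm) of the corner of voxel (0, 0, 0).
    axis_order : str
        Axis-convention tag; ``"sagittal"`` means slices along axis 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "sagittal"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if any(n < 2 for n in values.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {values.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm (voxel-corner origin)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return replace(self, values=values)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid sharing :class:`VoxelGrid` geometry.

    ``side`` and ``rater`` are metadata supplied with the traces (left/right
    identity is not inferred from image laterality).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    side: str | None = None
    rater: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values).astype(bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.side is not None and self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.rater is not None and self.rater not in (1, 2):
            raise ValueError(f"rater must be 1 or 2, got {self.rater!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    def volume_cm3(self) -> float:
        """Voxel-count volume in cm^3."""
        return self.n_true * float(np.prod(self.spacing)) / 1000.0

    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class TraceSlice:
    """Closed polygons traced on one sagittal slice (coordinates in mm)."""

    index: int
    polygons: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        polys = []
        for poly in self.polygons:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("each polygon must be an (n, 2) array of mm coords")
            # drop an explicit closing vertex; closure is implicit
            if len(arr) >= 2 and np.allclose(arr[0], arr[-1]):
                arr = arr[:-1]
            if len(arr) < 3:
                raise ValueError("each polygon needs >= 3 distinct vertices")
            polys.append(arr)
        object.__setattr__(self, "polygons", tuple(polys))
        if self.index < 0:
            raise ValueError("slice index must be non-negative")


@dataclass(frozen=True)
class TracePolygonSet:
    """Per-slice manual trace polygons for one hippocampus of one patient."""

    patient: str
    rater: int
    side: str
    slices: tuple[TraceSlice, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.rater not in (1, 2):
            raise ValueError(f"rater must be 1 or 2, got {self.rater!r}")


def voxel_centers_1d(n: int, spacing: float, origin: float = 0.0) -> np.ndarray:
    """Physical center coordinates of ``n`` voxels along one axis."""
    return origin + (np.arange(n) + 0.5) * spacing


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------


def write_volume(grid: VoxelGrid | BinaryMask, path: str | Path) -> None:
    """Write a grid as a NIfTI-1 file; masks are stored as uint8."""
    path = Path(path)
    if isinstance(grid, BinaryMask):
        data = grid.values.astype(np.uint8)
    else:
        data = np.asarray(grid.values)
    img = nib.Nifti1Image(data, grid.affine())
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a NIfTI file or a directory holding a single DICOM series.

    DICOM slices are sorted by ImagePositionPatient along the slice normal
    (falling back to InstanceNumber) and a single series is enforced.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    _notice_anisotropy(zooms)
    return VoxelGrid(values=data, spacing=zooms, origin=origin)


def _notice_anisotropy(spacing: Sequence[float]) -> None:
    if max(spacing) / min(spacing) > 1.001:
        logger.info("anisotropic voxel spacing %s (allowed)", tuple(spacing))


def _read_dicom_series(directory: Path) -> VoxelGrid:
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM files in the directory are skipped
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory {directory} mixes {len(uids)} DICOM series")

    def _sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=_sort_key)
    first = datasets[0]
    pixel_spacing = getattr(first, "PixelSpacing", None)
    if pixel_spacing is None:
        raise ValueError("DICOM series missing PixelSpacing")
    if len(datasets) >= 2:
        p0 = getattr(datasets[0], "ImagePositionPatient", None)
        p1 = getattr(datasets[1], "ImagePositionPatient", None)
        if p0 is not None and p1 is not None:
            slice_spacing = float(abs(float(p1[2]) - float(p0[2])))
        else:
            slice_spacing = float(getattr(first, "SliceThickness", 1.0))
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))
    if slice_spacing <= 0:
        raise ValueError("could not determine a positive DICOM slice spacing")
    slices = [ds.pixel_array.astype(np.float64) for ds in datasets]
    # slices stack along axis 0 (sagittal convention)
    data = np.stack(slices, axis=0)
    spacing = (slice_spacing, float(pixel_spacing[0]), float(pixel_spacing[1]))
    _notice_anisotropy(spacing)
    pos = getattr(first, "ImagePositionPatient", (0.0, 0.0, 0.0))
    origin = (float(pos[2]), float(pos[0]), float(pos[1]))
    return VoxelGrid(values=data, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Trace JSON interchange
# ---------------------------------------------------------------------------
# Schema: {"patient": str, "rater": int, "side": "left"|"right",
#          "slices": [{"index": int, "polygons": [[[x, y], ...], ...]}]}


def write_traces(traces: TracePolygonSet, path: str | Path) -> None:
    doc = {
        "patient": traces.patient,
        "rater": traces.rater,
        "side": traces.side,
        "slices": [
            {"index": s.index, "polygons": [p.tolist() for p in s.polygons]}
            for s in traces.slices
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_traces(path: str | Path) -> TracePolygonSet:
    doc = json.loads(Path(path).read_text())
    slices = tuple(
        TraceSlice(index=int(s["index"]), polygons=tuple(np.asarray(p) for p in s["polygons"]))
        for s in doc["slices"]
    )
    return TracePolygonSet(
        patient=str(doc["patient"]), rater=int(doc["rater"]), side=str(doc["side"]),
        slices=slices,
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized.

    A point is inside when a ray to +x crosses the boundary an odd number of
    times.  The even-odd rule makes the result independent of vertex
    orientation and well defined for self-intersecting polygons.
    """
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    px, py = polygon[:, 0], polygon[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    for x1, y1, x2, y2 in zip(px, py, qx, qy):
        crosses = (y1 > y) != (y2 > y)
        if not crosses.any():
            continue
        x_at_y = x1 + (y[crosses] - y1) * (x2 - x1) / (y2 - y1)
        hits = np.zeros_like(inside)
        hits[crosses] = x[crosses] < x_at_y
        inside ^= hits
    return inside


def _polygon_is_simple(polygon: np.ndarray) -> bool:
    """Cheap self-intersection check (O(n^2) segment pairs)."""
    n = len(polygon)
    segs = [(polygon[i], polygon[(i + 1) % n]) for i in range(n)]

    def _cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = _cross(p3, p4, p1), _cross(p3, p4, p2)
            d3, d4 = _cross(p1, p2, p3), _cross(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return False
    return True


def traces_to_mask(traces: TracePolygonSet, grid: VoxelGrid) -> BinaryMask:
    """Rasterize per-slice trace polygons into a binary mask on ``grid``.

    Per slice, voxel centers inside any polygon (even-odd rule) are set true;
    multiple polygons on a slice are OR-combined.  Polygon parts outside the
    slice extent are clipped with a warning.
    """
    nx, ny, nz = grid.shape
    mask = np.zeros(grid.shape, dtype=bool)
    yc = voxel_centers_1d(ny, grid.spacing[1], grid.origin[1])
    zc = voxel_centers_1d(nz, grid.spacing[2], grid.origin[2])
    yy, zz = np.meshgrid(yc, zc, indexing="ij")
    pts = np.column_stack([yy.ravel(), zz.ravel()])
    y_max = grid.origin[1] + ny * grid.spacing[1]
    z_max = grid.origin[2] + nz * grid.spacing[2]
    for sl in traces.slices:
        if not (0 <= sl.index < nx):
            raise ValueError(
                f"slice index {sl.index} outside volume with {nx} slices"
            )
        plane = np.zeros(ny * nz, dtype=bool)
        for poly in sl.polygons:
            if (poly[:, 0].min() < grid.origin[1] or poly[:, 0].max() > y_max
                    or poly[:, 1].min() < grid.origin[2] or poly[:, 1].max() > z_max):
                warnings.warn(
                    f"polygon on slice {sl.index} extends outside the slice "
                    "bounds; it is clipped to the grid", stacklevel=2)
            if not _polygon_is_simple(poly):
                warnings.warn(
                    f"self-intersecting polygon on slice {sl.index}; filled "
                    "with the even-odd rule", stacklevel=2)
            plane |= _points_in_polygon(pts, poly)
        mask[sl.index] |= plane.reshape(ny, nz)
    return BinaryMask(values=mask, spacing=grid.spacing, origin=grid.origin,
                      side=traces.side, rater=traces.rater)
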