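"""Shared volumetric data model: grids, volumes, masks, contours, fields.

All physical coordinates are in the DICOM LPS patient frame, in millimetres:
x = patient left, y = posterior, z = superior (cranial). Voxel indexing is
0-based with voxel *centers* as sample points; arrays are indexed ``[i, j, k]``
along the (x, y, z) grid axes, i.e. ``values.shape == grid.size``.

The affine index->physical map is ``p = origin + direction @ (spacing * index)``
with an orthonormal ``direction`` matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import SimpleITK as sitk
from skimage import measure
from skimage.draw import polygon2mask


class InvalidGridError(ValueError):
    """Raised for grids with non-orthonormal direction or bad spacing."""


class ContourFormatError(ValueError):
    """Raised for degenerate or non-axial contour input."""


def _as_tuple3(v, dtype=float) -> tuple:
    t = tuple(dtype(x) for x in np.asarray(v).ravel())
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t


@dataclass(frozen=True)
class ImageGrid:
    """Geometric frame of a regular 3-D voxel grid in patient coordinates."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_tuple3(self.origin))
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing))
        object.__setattr__(self, "size", _as_tuple3(self.size, int))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if any(s <= 0 for s in self.spacing):
            raise InvalidGridError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise InvalidGridError(f"size must be >= 1 per axis, got {self.size}")
        if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
            raise InvalidGridError("direction matrix is not orthonormal")

    # -- affine index <-> physical maps ------------------------------------
    def index_to_physical(self, index) -> np.ndarray:
        """Map (fractional) voxel indices to physical points in mm.

        Accepts a single index triple or an (N, 3) array; returns the same
        shape with float mm coordinates.
        """
        idx = np.asarray(index, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + scaled @ self.direction.T

    def physical_to_index(self, point) -> np.ndarray:
        """Inverse of :meth:`index_to_physical` (fractional indices)."""
        p = np.asarray(point, dtype=float)
        local = (p - np.asarray(self.origin)) @ self.direction
        return local / np.asarray(self.spacing)

    # -- conveniences ------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical x/y/z coordinates of every voxel center, each shaped ``size``.

        Requires an axis-aligned grid only in the sense that the full affine
        map is applied; works for any orthonormal direction.
        """
        ii, jj, kk = np.meshgrid(
            np.arange(self.size[0]),
            np.arange(self.size[1]),
            np.arange(self.size[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).astype(float)
        phys = self.index_to_physical(idx.reshape(-1, 3)).reshape(*self.size, 3)
        return phys[..., 0], phys[..., 1], phys[..., 2]

    def same_geometry(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def to_sitk_reference(self) -> sitk.Image:
        img = sitk.Image(int(self.size[0]), int(self.size[1]), int(self.size[2]), sitk.sitkFloat64)
        img.SetOrigin(self.origin)
        img.SetSpacing(self.spacing)
        img.SetDirection(tuple(self.direction.ravel()))
        return img


@dataclass
class ScalarVolume:
    """A scalar image (CBCT intensities, Jacobian maps, ...) on a grid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.size):
            raise ValueError(
                f"value shape {self.values.shape} != grid size {self.grid.size}"
            )


@dataclass
class BinaryMask:
    """A segmented organ as a boolean voxel mask."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != tuple(self.grid.size):
            raise ValueError(
                f"mask shape {self.values.shape} != grid size {self.grid.size}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_cc(self) -> float:
        """Foreground volume in cubic centimetres."""
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class ContourSet:
    """Planar axial contours: list of (z position mm, list of (N,2) xy-mm polygons)."""

    slices: list[tuple[float, list[np.ndarray]]]

    def __post_init__(self):
        for z, polys in self.slices:
            for p in polys:
                p = np.asarray(p, dtype=float)
                if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                    raise ContourFormatError(
                        "each polygon needs >= 3 planar (x, y) vertices"
                    )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacements in mm, patient axes, pull-back convention.

    The field lives on its (fixed) grid; the warp it encodes maps a fixed-frame
    point x to x + d(x) in the moving frame, and resampling an image through it
    is ``out(x) = img(x + d(x))``.
    """

    grid: ImageGrid
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (*self.grid.size, 3):
            raise ValueError(
                f"vector shape {self.vectors.shape} != grid size {self.grid.size} x 3"
            )

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    @classmethod
    def zero(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(grid, np.zeros((*grid.size, 3)))


@dataclass
class DoseGrid:
    """Absorbed dose per voxel in Gy."""

    grid: ImageGrid
    dose: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != tuple(self.grid.size):
            raise ValueError(
                f"dose shape {self.dose.shape} != grid size {self.grid.size}"
            )
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValueError("dose values must be finite and non-negative")


# ---------------------------------------------------------------------------
# SimpleITK interchange
# ---------------------------------------------------------------------------

def to_sitk(vol: ScalarVolume | BinaryMask | DoseGrid) -> sitk.Image:
    """Convert to a SimpleITK image (reorders axes to ITK's z,y,x memory layout)."""
    arr = vol.values if not isinstance(vol, DoseGrid) else vol.dose
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetOrigin(vol.grid.origin)
    img.SetSpacing(vol.grid.spacing)
    img.SetDirection(tuple(vol.grid.direction.ravel()))
    return img


def field_to_sitk(dvf: DisplacementField) -> sitk.Image:
    arr = np.ascontiguousarray(dvf.vectors.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetOrigin(dvf.grid.origin)
    img.SetSpacing(dvf.grid.spacing)
    img.SetDirection(tuple(dvf.grid.direction.ravel()))
    return img


def grid_from_sitk(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        origin=img.GetOrigin(),
        spacing=img.GetSpacing(),
        size=img.GetSize(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def scalar_from_sitk(img: sitk.Image) -> ScalarVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ScalarVolume(grid_from_sitk(img), arr)


def mask_from_sitk(img: sitk.Image) -> BinaryMask:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return BinaryMask(grid_from_sitk(img), arr > 0)


def field_from_sitk(img: sitk.Image) -> DisplacementField:
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected a 3-component vector image")
    return DisplacementField(grid_from_sitk(img), arr.transpose(2, 1, 0, 3))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "trilinear": sitk.sitkLinear}


def resample_scalar(
    src: ScalarVolume,
    target: ImageGrid,
    interpolation: Literal["nearest", "trilinear"] = "trilinear",
    fill: float = 0.0,
) -> ScalarVolume:
    """Resample a scalar volume onto another grid.

    Trilinear output is convex in the source values; points outside the source
    extent take ``fill``.
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    img = to_sitk(src)
    out = sitk.Resample(
        img,
        target.to_sitk_reference(),
        sitk.Transform(),
        _INTERPOLATORS[interpolation],
        float(fill),
        sitk.sitkFloat64,
    )
    return ScalarVolume(target, sitk.GetArrayFromImage(out).transpose(2, 1, 0))


def resample_mask(mask: BinaryMask, target: ImageGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a mask onto another grid."""
    if mask.grid.same_geometry(target):
        return mask
    sv = resample_scalar(
        ScalarVolume(mask.grid, mask.values.astype(np.float64)), target, "nearest", 0.0
    )
    return BinaryMask(target, sv.values > 0.5)


def dilate_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Isotropic dilation by a physical margin (e.g. CTV -> PTV expansion)."""
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    if margin_mm == 0:
        return BinaryMask(mask.grid, mask.values.copy())
    from scipy.ndimage import distance_transform_edt

    dist = distance_transform_edt(~mask.values, sampling=mask.grid.spacing)
    return BinaryMask(mask.grid, mask.values | (dist <= margin_mm))


def sample_at_physical(
    values: np.ndarray,
    grid: ImageGrid,
    points: np.ndarray,
    interpolation: Literal["nearest", "trilinear"] = "trilinear",
    fill: float = 0.0,
) -> np.ndarray:
    """Sample a gridded array at arbitrary physical points (mm).

    ``values`` has shape ``grid.size`` (scalar) or ``grid.size + (C,)``
    (vector, sampled per component). ``points`` is (..., 3); the result keeps
    the leading shape. Points outside the grid extent take ``fill``.
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(points, dtype=float)
    lead = pts.shape[:-1]
    idx = grid.physical_to_index(pts.reshape(-1, 3)).T  # (3, N)
    order = 0 if interpolation == "nearest" else 1
    if values.ndim == 3:
        out = map_coordinates(
            values.astype(float), idx, order=order, mode="constant", cval=fill
        )
        return out.reshape(lead)
    comps = [
        map_coordinates(
            values[..., c].astype(float), idx, order=order, mode="constant", cval=fill
        )
        for c in range(values.shape[-1])
    ]
    return np.stack(comps, axis=-1).reshape(*lead, values.shape[-1])


# ---------------------------------------------------------------------------
# Contours <-> masks (RTSTRUCT interchange, axial planes only)
# ---------------------------------------------------------------------------

def mask_to_contours(mask: BinaryMask) -> ContourSet:
    """Extract closed axial polygons at the 0.5 iso-level of a mask.

    Empty masks yield an empty ContourSet. The grid must be axis-aligned
    (identity-like direction) since contours are defined on constant-z planes.
    """
    if not np.allclose(np.abs(mask.grid.direction), np.eye(3), atol=1e-6):
        raise ContourFormatError("contour extraction requires an axis-aligned grid")
    slices: list[tuple[float, list[np.ndarray]]] = []
    for k in range(mask.grid.size[2]):
        sl = mask.values[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        z = float(mask.grid.index_to_physical((0, 0, k))[2])
        polys = []
        for c in measure.find_contours(padded, 0.5):
            ij = c - 1.0  # undo padding; columns are (i, j) fractional indices
            n = ij.shape[0]
            idx3 = np.column_stack([ij, np.full(n, k, dtype=float)])
            xy = mask.grid.index_to_physical(idx3)[:, :2]
            if np.allclose(xy[0], xy[-1]):
                xy = xy[:-1]
            if xy.shape[0] >= 3:
                polys.append(xy)
        if polys:
            slices.append((z, polys))
    return ContourSet(slices)


def contours_to_mask(cs: ContourSet, grid: ImageGrid) -> BinaryMask:
    """Rasterize axial polygons onto a grid (even-odd rule, so holes nest)."""
    if not np.allclose(np.abs(grid.direction), np.eye(3), atol=1e-6):
        raise ContourFormatError("rasterization requires an axis-aligned grid")
    out = np.zeros(grid.size, dtype=bool)
    for z, polys in cs.slices:
        k_f = grid.physical_to_index((grid.origin[0], grid.origin[1], z))[2]
        k = int(round(k_f))
        if not (0 <= k < grid.size[2]):
            continue
        sl = np.zeros(grid.size[:2], dtype=bool)
        for poly in polys:
            poly = np.asarray(poly, dtype=float)
            n = poly.shape[0]
            idx3 = grid.physical_to_index(
                np.column_stack([poly, np.full(n, z)])
            )[:, :2]
            filled = polygon2mask(grid.size[:2], idx3)
            sl ^= filled  # even-odd: inner contours carve holes
        out[:, :, k] |= sl
    return BinaryMask(grid, out)
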