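"""Geometric comparison of planning vs. verification bladder segmentations.

The on-couch adaptation interval of CBCT-guided online adaptive radiotherapy
is bracketed by a planning CBCT (pCBCT) and a verification CBCT (vCBCT).
This module quantifies how much the bladder changed in between: volume change
and expansion rate (cc/min), boundary-distance metrics (directed Hausdorff
distance and its robust 95th-percentile variant, HD95%), and the Dice
similarity coefficient DSC = 2|A∩B| / (|A| + |B|).

The Hausdorff distance is directed (planning -> verification) by default and,
in ``slice2d`` mode, restricts the nearest-point search to the same axial
plane, reflecting the slice-wise way such contours are drawn and reviewed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import BinaryMask, resample_mask


class UndefinedMetricError(ValueError):
    """A metric was requested on empty input where it has no value."""


class ChronologyError(ValueError):
    """Verification timestamp does not follow the planning timestamp."""


@dataclass
class GeometricReport:
    """Per-fraction geometric comparison row."""

    volume_p: float  # cc
    volume_v: float  # cc
    delta_cc: float
    relative_change: float  # percent of planning volume
    expansion_rate: float  # cc/min
    dt: float  # min
    hd95: float  # mm
    hd_max: float  # mm
    dsc: float


def volume_cc(mask: BinaryMask) -> float:
    """Foreground volume in cc (voxel count x voxel volume)."""
    return mask.volume_cc()


def _minutes_between(t_p, t_v) -> float:
    if isinstance(t_p, _dt.datetime) and isinstance(t_v, _dt.datetime):
        return (t_v - t_p).total_seconds() / 60.0
    return float(t_v) - float(t_p)


def expansion_rate(volume_p: float, volume_v: float, t_p, t_v) -> float:
    """Bladder volume change per unit time, cc/min (negative = shrinkage).

    Timestamps may be datetimes or already-minutes floats.
    """
    dt = _minutes_between(t_p, t_v)
    if dt <= 0:
        raise ChronologyError("verification time must follow planning time")
    return (volume_v - volume_p) / dt


def boundary_voxels(mask: BinaryMask) -> np.ndarray:
    """Boolean array marking face-connected boundary voxels of the foreground."""
    eroded = ndimage.binary_erosion(
        mask.values, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask.values & ~eroded


def _boundary_points_mm(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """(N,3) physical coordinates of boundary voxel centers, plus their k indices."""
    idx = np.argwhere(boundary_voxels(mask))
    if idx.size == 0:
        raise UndefinedMetricError("mask has no foreground; boundary undefined")
    return mask.grid.index_to_physical(idx.astype(float)), idx[:, 2]


def hausdorff_percentile(
    mask_a: BinaryMask,
    mask_b: BinaryMask,
    percentile: float = 95.0,
    mode: str = "slice2d",
    symmetric: bool = False,
) -> float:
    """Percentile of directed boundary distances from ``mask_a`` to ``mask_b``, mm.

    ``percentile=100`` gives the directed Hausdorff maximum. ``slice2d``
    searches nearest boundary points within the same axial slice (slices of
    ``mask_a`` with no counterpart in ``mask_b`` fall back to a 3-D search);
    ``full3d`` always searches in 3-D. With ``symmetric=True`` distances from
    both directions are pooled before taking the percentile.
    """
    if mode not in ("slice2d", "full3d"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 <= percentile <= 100):
        raise ValueError("percentile must be in [0, 100]")
    if not mask_b.grid.same_geometry(mask_a.grid):
        mask_b = resample_mask(mask_b, mask_a.grid)
    dists = _directed_boundary_distances(mask_a, mask_b, mode)
    if symmetric:
        dists = np.concatenate(
            [dists, _directed_boundary_distances(mask_b, mask_a, mode)]
        )
    return float(np.percentile(dists, percentile, method="linear"))


def _directed_boundary_distances(
    mask_a: BinaryMask, mask_b: BinaryMask, mode: str
) -> np.ndarray:
    pts_a, k_a = _boundary_points_mm(mask_a)
    pts_b, k_b = _boundary_points_mm(mask_b)
    if mode == "full3d":
        return cKDTree(pts_b).query(pts_a)[0]
    tree3d = cKDTree(pts_b)
    dists = np.empty(len(pts_a))
    trees2d = {
        k: cKDTree(pts_b[k_b == k][:, :2]) for k in np.unique(k_b)
    }
    for k in np.unique(k_a):
        sel = k_a == k
        if k in trees2d:
            dists[sel] = trees2d[k].query(pts_a[sel][:, :2])[0]
        else:  # slice exists in only one mask: 3-D fallback
            dists[sel] = tree3d.query(pts_a[sel])[0]
    return dists


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity coefficient, 2|A∩B| / (|A| + |B|)."""
    if not mask_b.grid.same_geometry(mask_a.grid):
        mask_b = resample_mask(mask_b, mask_a.grid)
    a, b = mask_a.values, mask_b.values
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise UndefinedMetricError("DSC undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / denom


def geometric_report(
    bladder_p: BinaryMask,
    bladder_v: BinaryMask,
    t_p,
    t_v,
    hd_mode: str = "slice2d",
) -> GeometricReport:
    """Full per-fraction geometric comparison of the planning/verification pair."""
    vp, vv = volume_cc(bladder_p), volume_cc(bladder_v)
    dt = _minutes_between(t_p, t_v)
    rate = expansion_rate(vp, vv, t_p, t_v)
    return GeometricReport(
        volume_p=vp,
        volume_v=vv,
        delta_cc=vv - vp,
        relative_change=100.0 * (vv - vp) / vp if vp > 0 else np.nan,
        expansion_rate=rate,
        dt=dt,
        hd95=hausdorff_percentile(bladder_p, bladder_v, 95.0, hd_mode),
        hd_max=hausdorff_percentile(bladder_p, bladder_v, 100.0, hd_mode),
        dsc=dice(bladder_p, bladder_v),
    )
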