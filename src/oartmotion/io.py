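"""Readers and writers for the standard radiotherapy interchange formats.

Volumes, masks and 3-component displacement fields round-trip through NIfTI
(``.nii``/``.nii.gz``) and MetaImage (``.mha``/``.mhd``) via SimpleITK. DICOM
input covers CT/CBCT image series, RTSTRUCT contours and RTDOSE grids via
pydicom. All geometry is interpreted in the DICOM LPS patient frame.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

from .geometry import (
    BinaryMask,
    ContourSet,
    DisplacementField,
    DoseGrid,
    ImageGrid,
    ScalarVolume,
    contours_to_mask,
    field_from_sitk,
    field_to_sitk,
    mask_from_sitk,
    scalar_from_sitk,
    to_sitk,
)

# -- volume files -----------------------------------------------------------

def write_scalar(vol: ScalarVolume | DoseGrid, path: str | Path) -> None:
    sitk.WriteImage(to_sitk(vol), str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    sitk.WriteImage(to_sitk(mask), str(path))


def write_field(dvf: DisplacementField, path: str | Path) -> None:
    """Write a displacement field (mm, patient axes, pull-back convention)."""
    img = field_to_sitk(dvf)
    # Convention note travels in the metadata where the format allows it.
    img.SetMetaData("displacement_convention", "fixed-frame pull-back, mm, LPS")
    sitk.WriteImage(img, str(path))


def read_scalar(path: str | Path) -> ScalarVolume:
    return scalar_from_sitk(sitk.ReadImage(str(path), sitk.sitkFloat64))


def read_mask(path: str | Path) -> BinaryMask:
    return mask_from_sitk(sitk.ReadImage(str(path)))


def read_dose(path: str | Path) -> DoseGrid:
    sv = read_scalar(path)
    return DoseGrid(sv.grid, sv.values)


def read_field(path: str | Path) -> DisplacementField:
    return field_from_sitk(sitk.ReadImage(str(path), sitk.sitkVectorFloat64))


# -- DICOM image series -----------------------------------------------------

def read_dicom_series(directory: str | Path) -> ScalarVolume:
    """Read a CT/CBCT DICOM series from a directory into a scalar volume."""
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FileNotFoundError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    return scalar_from_sitk(sitk.Cast(reader.Execute(), sitk.sitkFloat64))


def read_acquisition_time(path: str | Path) -> _dt.datetime:
    """Acquisition timestamp from a DICOM file, or from a JSON sidecar.

    DICOM: AcquisitionDate + AcquisitionTime (falling back to Series/Content
    tags). JSON sidecar: ``{"acquisition_time": "<ISO-8601>"}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _dt.datetime.fromisoformat(json.load(fh)["acquisition_time"])
    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    for date_tag, time_tag in (
        ("AcquisitionDate", "AcquisitionTime"),
        ("SeriesDate", "SeriesTime"),
        ("ContentDate", "ContentTime"),
    ):
        d, t = getattr(ds, date_tag, None), getattr(ds, time_tag, None)
        if d and t:
            frac = 0.0
            if "." in str(t):
                t, frac_s = str(t).split(".")
                frac = float("0." + frac_s)
            base = _dt.datetime.strptime(str(d) + str(t), "%Y%m%d%H%M%S")
            return base + _dt.timedelta(seconds=frac)
    raise ValueError(f"no acquisition timestamp in {path}")


# -- RTSTRUCT ---------------------------------------------------------------

def read_rtstruct_contours(path: str | Path, roi_name: str) -> ContourSet:
    """Extract one ROI from an RTSTRUCT as axial polygons (mm, patient frame)."""
    ds = pydicom.dcmread(str(path))
    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    number = None
    for num, name in names.items():
        if name.lower() == roi_name.lower():
            number = num
    if number is None:
        raise KeyError(f"ROI {roi_name!r} not in {sorted(names.values())}")
    by_z: dict[float, list[np.ndarray]] = {}
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) != number:
            continue
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            z_vals = pts[:, 2]
            if np.ptp(z_vals) > 1e-3:
                raise ValueError("non-axial RTSTRUCT contour is not supported")
            by_z.setdefault(round(float(z_vals[0]), 3), []).append(pts[:, :2])
    slices = [(z, polys) for z, polys in sorted(by_z.items())]
    return ContourSet(slices)


def read_rtstruct_mask(path: str | Path, roi_name: str, grid: ImageGrid) -> BinaryMask:
    return contours_to_mask(read_rtstruct_contours(path, roi_name), grid)


def rtstruct_roi_names(path: str | Path) -> list[str]:
    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    return [str(r.ROIName) for r in ds.StructureSetROISequence]


# -- RTDOSE -----------------------------------------------------------------

def read_rtdose(path: str | Path) -> DoseGrid:
    """Read an RTDOSE grid, applying DoseGridScaling, into Gy."""
    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(np.float64) * scaling  # frames are z-major
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    if len(offsets) > 2 and not np.allclose(np.diff(offsets), dz, atol=1e-3):
        raise ValueError("non-uniform RTDOSE frame spacing is not supported")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    z_dir = np.cross(row_dir, col_dir)
    direction = np.column_stack([row_dir, col_dir, z_dir])
    grid = ImageGrid(
        origin=origin,
        spacing=(col_sp, row_sp, abs(dz)),
        size=(arr.shape[2], arr.shape[1], arr.shape[0]),
        direction=direction,
    )
    return DoseGrid(grid, arr.transpose(2, 1, 0))
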