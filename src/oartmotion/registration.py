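"""Displacement fields between planning and verification CBCT.

The deformable algorithm is a Gaussian-regularized, demons-style,
multi-resolution registration (SimpleITK's symmetric-forces demons), run after
an optional rigid pre-alignment. Structure guidance — the bladder masks of the
two images, when available — is applied by adding a smoothed mask-contrast
channel to both images so the similarity gradient emphasizes the guided organ.

Convention (used everywhere in this package): a displacement field lives on
the *fixed* grid and has pull-back semantics, ``out(x) = moving(x + d(x))``.
With fixed = vCBCT and moving = pCBCT, ``x + d(x)`` maps a verification-frame
point to its planning-frame (pre-motion) position. Registration quality is
validated with the Dice similarity coefficient between the warped moving
bladder and the fixed bladder, the same criterion used to accept clinical DIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Optional

import numpy as np
import SimpleITK as sitk

from .geometry import (
    BinaryMask,
    DisplacementField,
    ImageGrid,
    ScalarVolume,
    field_from_sitk,
    sample_at_physical,
    to_sitk,
)


class RegistrationDomainError(ValueError):
    """Fixed and moving image extents do not overlap."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for the built-in deformable registration.

    ``smoothing_sigmas`` regularize the displacement field, in mm per level;
    ``None`` means 1.5 voxels at each level's resolution. Registration is
    deterministic (dense similarity evaluation, no random sampling).
    """

    similarity: str = "mutual_information"  # used by the rigid stage
    levels: int = 5
    iterations: tuple = (100, 80, 60, 30, 10)
    smoothing_sigmas: Optional[tuple] = None
    rigid_first: bool = True
    guidance_weight: float = 1.0  # mask-contrast channel, relative to image range

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.iterations) < self.levels or any(
            i <= 0 for i in self.iterations[: self.levels]
        ):
            raise ValueError("need a positive iteration count per level")


@dataclass
class RigidTransform:
    """Six-parameter (Euler angles + translation) rigid map, fixed -> moving."""

    rotation_rad: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter(self.center_mm)
        t.SetRotation(*self.rotation_rad)
        t.SetTranslation(self.translation_mm)
        return t

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-frame physical points into the moving frame."""
        m = np.asarray(self.to_sitk().GetMatrix()).reshape(3, 3)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        p = np.asarray(points, dtype=float)
        return (p - c) @ m.T + c + t

    @property
    def parameters(self) -> tuple:
        return (*self.rotation_rad, *self.translation_mm)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))


@dataclass
class RegistrationResult:
    dvf: DisplacementField
    rigid: Optional[RigidTransform]
    validation_dsc: Optional[float]
    converged: bool
    level_metrics: list = _dc_field(default_factory=list)
    jacobian_positive_fraction: Optional[float] = None


# ---------------------------------------------------------------------------
# Rigid stage
# ---------------------------------------------------------------------------

def _check_overlap(fixed: ImageGrid, moving: ImageGrid) -> None:
    def bounds(g: ImageGrid):
        corners = np.array(
            [[i, j, k] for i in (0, g.size[0] - 1) for j in (0, g.size[1] - 1)
             for k in (0, g.size[2] - 1)],
            dtype=float,
        )
        pts = g.index_to_physical(corners)
        return pts.min(axis=0), pts.max(axis=0)

    lo_f, hi_f = bounds(fixed)
    lo_m, hi_m = bounds(moving)
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise RegistrationDomainError("image extents do not overlap")


def rigid_register(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    similarity: str = "mutual_information",
) -> RigidTransform:
    """Recover the rigid (rotation + translation) alignment fixed -> moving."""
    _check_overlap(fixed.grid, moving.grid)
    f = sitk.Cast(to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(to_sitk(moving), sitk.sitkFloat32)
    reg = sitk.ImageRegistrationMethod()
    if similarity == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    elif similarity == "mean_squares":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=80,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel([4, 2])
    reg.SetSmoothingSigmasPerLevel([4.0, 2.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    out = reg.Execute(f, m)
    euler = sitk.Euler3DTransform(out.GetNthTransform(0) if isinstance(out, sitk.CompositeTransform) else out)
    return RigidTransform(
        rotation_rad=tuple(euler.GetParameters()[:3]),
        translation_mm=tuple(euler.GetParameters()[3:]),
        center_mm=tuple(euler.GetCenter()),
    )


# ---------------------------------------------------------------------------
# Deformable stage
# ---------------------------------------------------------------------------

def _augment(img: sitk.Image, mask: Optional[BinaryMask], weight: float,
             contrast: float) -> sitk.Image:
    if mask is None or weight == 0:
        return img
    m = sitk.Cast(to_sitk(mask), sitk.sitkFloat32)
    m = sitk.Resample(m, img, sitk.Transform(), sitk.sitkLinear, 0.0)
    m = sitk.SmoothingRecursiveGaussian(m, 2.0)
    return img + m * float(weight * contrast)


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    sig = [0.5 * factor * s for s in img.GetSpacing()]
    sm = sitk.SmoothingRecursiveGaussian(img, sig)
    new_size = [max(2, int(round(n / factor))) for n in img.GetSize()]
    new_spacing = [s * n / ns for s, n, ns in zip(img.GetSpacing(), img.GetSize(), new_size)]
    ref = sitk.Image(new_size, sitk.sitkFloat32)
    ref.SetOrigin(img.GetOrigin())
    ref.SetDirection(img.GetDirection())
    ref.SetSpacing(new_spacing)
    # keep voxel centers aligned with the original extent
    return sitk.Resample(sm, ref, sitk.Transform(), sitk.sitkLinear, 0.0)


def deformable_register(
    fixed: ScalarVolume,
    moving: ScalarVolume,
    cfg: RegistrationConfig = RegistrationConfig(),
    fixed_mask: Optional[BinaryMask] = None,
    moving_mask: Optional[BinaryMask] = None,
) -> RegistrationResult:
    """Demons-style deformable registration, fixed frame, pull-back field.

    When bladder masks are supplied they serve double duty: structure guidance
    during optimization and DSC validation of the result (warped moving
    bladder vs. fixed bladder).
    """
    _check_overlap(fixed.grid, moving.grid)
    rigid = None
    if cfg.rigid_first:
        rigid = rigid_register(fixed, moving, cfg.similarity)

    f_img = sitk.Cast(to_sitk(fixed), sitk.sitkFloat32)
    m_img = sitk.Cast(to_sitk(moving), sitk.sitkFloat32)
    rng = float(np.percentile(fixed.values, 99) - np.percentile(fixed.values, 1))
    rng = rng if rng > 0 else 1.0
    f_img = _augment(f_img, fixed_mask, cfg.guidance_weight, rng)
    if moving_mask is not None:
        m_img = _augment(m_img, moving_mask, cfg.guidance_weight, rng)
    # apply the rigid stage by resampling the moving image onto the fixed grid
    tfm = rigid.to_sitk() if rigid is not None else sitk.Transform()
    m_img = sitk.Resample(m_img, f_img, tfm, sitk.sitkLinear, 0.0)

    shrinks = [2 ** (cfg.levels - 1 - i) for i in range(cfg.levels)]
    disp = None
    level_metrics: list[list[float]] = []
    for level, shrink in enumerate(shrinks):
        f_l = _shrink(f_img, shrink)
        m_l = _shrink(m_img, shrink)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(cfg.iterations[level]))
        demons.SmoothDisplacementFieldOn()
        if cfg.smoothing_sigmas is not None:
            sigma_vox = cfg.smoothing_sigmas[level] / f_l.GetSpacing()[0]
        else:
            sigma_vox = 1.5
        demons.SetStandardDeviations(float(max(sigma_vox, 0.5)))
        trace: list[float] = []
        demons.AddCommand(sitk.sitkIterationEvent, lambda d=demons, t=trace: t.append(d.GetMetric()))
        if disp is None:
            disp = demons.Execute(f_l, m_l)
        else:
            disp = sitk.Resample(disp, f_l, sitk.Transform(), sitk.sitkLinear)
            disp = demons.Execute(f_l, m_l, disp)
        level_metrics.append(trace)

    disp = sitk.Resample(disp, f_img, sitk.Transform(), sitk.sitkLinear)
    demons_field = field_from_sitk(sitk.Cast(disp, sitk.sitkVectorFloat64))

    # total map: x -> rigid(x + d_demons(x)); expressed as one pull-back field
    if rigid is not None:
        xs, ys, zs = fixed.grid.coordinate_arrays()
        pts = np.stack([xs, ys, zs], axis=-1) + demons_field.vectors
        total = rigid.apply(pts.reshape(-1, 3)).reshape(pts.shape) - np.stack(
            [xs, ys, zs], axis=-1
        )
        dvf = DisplacementField(fixed.grid, total)
    else:
        dvf = demons_field

    # divergence = the similarity worsened across the final full-resolution
    # level; coarser levels restart from resampled fields and may jitter
    final_trace = level_metrics[-1]
    converged = len(final_trace) < 2 or final_trace[-1] <= final_trace[0]
    validation = None
    if fixed_mask is not None and moving_mask is not None:
        from .contour_metrics import dice

        warped = warp_mask(moving_mask, dvf)
        validation = dice(fixed_mask, warped)
    return RegistrationResult(
        dvf=dvf,
        rigid=rigid,
        validation_dsc=validation,
        converged=converged,
        level_metrics=level_metrics,
    )


# ---------------------------------------------------------------------------
# Field algebra
# ---------------------------------------------------------------------------

def _warp_points(dvf: DisplacementField) -> np.ndarray:
    xs, ys, zs = dvf.grid.coordinate_arrays()
    return np.stack([xs, ys, zs], axis=-1) + dvf.vectors


def warp_mask(
    mask: BinaryMask,
    dvf: DisplacementField,
    interpolation: str = "trilinear",
) -> BinaryMask:
    """Pull a mask into the field's (fixed) frame: out(x) = mask(x + d(x)).

    The default anti-aliases the binary indicator (Gaussian, 0.7 voxel) and
    samples it with trilinear interpolation, thresholding at 0.5 — this
    recovers the segmented surface to sub-voxel accuracy, which plain
    nearest-neighbour pull-back (``interpolation="nearest"``) cannot.
    """
    pts = _warp_points(dvf)
    if interpolation == "nearest":
        vals = sample_at_physical(
            mask.values.astype(np.float64), mask.grid, pts, "nearest", 0.0
        )
    else:
        from scipy.ndimage import gaussian_filter

        smoothed = gaussian_filter(mask.values.astype(np.float64), sigma=0.7)
        vals = sample_at_physical(smoothed, mask.grid, pts, "trilinear", 0.0)
    return BinaryMask(dvf.grid, vals >= 0.5)


def warp_scalar(vol: ScalarVolume, dvf: DisplacementField,
                fill: float = 0.0) -> ScalarVolume:
    """Pull a scalar volume into the field's frame with trilinear sampling."""
    pts = _warp_points(dvf)
    vals = sample_at_physical(vol.values, vol.grid, pts, "trilinear", fill)
    return ScalarVolume(dvf.grid, vals)


def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Compose two pull-back fields: d(x) = d_in(x) + d_out(x + d_in(x)).

    The result, on the inner field's grid, encodes applying ``inner`` first
    and then ``outer`` — e.g. expressing per-fraction pCBCT->vCBCT motion in a
    common planning-CT frame for cross-fraction comparison.
    """
    pts = _warp_points(inner)
    sampled = sample_at_physical(outer.vectors, outer.grid, pts, "trilinear", 0.0)
    return DisplacementField(inner.grid, inner.vectors + sampled)


def invert_field(
    dvf: DisplacementField,
    tolerance_voxel: float = 0.05,
    max_iterations: int = 50,
) -> DisplacementField:
    """Fixed-point inversion: find g with g(x) = -d(x + g(x)).

    Composing the result with ``dvf`` gives a near-identity map; iteration
    stops when the maximum update drops below ``tolerance_voxel`` voxels.
    """
    tol_mm = tolerance_voxel * min(dvf.grid.spacing)
    xs, ys, zs = dvf.grid.coordinate_arrays()
    base = np.stack([xs, ys, zs], axis=-1)
    g = np.zeros_like(dvf.vectors)
    for _ in range(max_iterations):
        sampled = sample_at_physical(dvf.vectors, dvf.grid, base + g, "trilinear", 0.0)
        new_g = -sampled
        delta = np.max(np.linalg.norm(new_g - g, axis=-1))
        g = new_g
        if delta < tol_mm:
            break
    return DisplacementField(dvf.grid, g)
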