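"""Dosimetric impact of intra-fractional motion: dose warping and DVH metrics.

The verification CBCT cannot support dose recalculation (its intensities are
not calibrated), so the "treated" dose on the verification anatomy is
estimated by warping the intended (planned) dose through the registration's
displacement field: ``treated(x) = intended(x + d(x))`` with a field that
maps verification-frame points to planning-frame points. Cumulative DVHs are
then computed per structure and the usual clinical metrics extracted:
Vx% (volume receiving >= x% of prescription), Dy% (minimum dose to the
hottest y% of volume) and Dc cc (minimum dose to the hottest c cm^3).

All doses are per fraction (Gy/fx); course dose is a plain sum, with no
radiobiological conversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contour_metrics import UndefinedMetricError
from .geometry import BinaryMask, DisplacementField, DoseGrid, resample_mask, sample_at_physical

#: relative tolerance when testing dose >= threshold, so that interpolation
#: round-off (e.g. a warped uniform dose at Rx*(1 - 1e-16)) does not drop a
#: voxel out of the bin it belongs to.
DOSE_RTOL = 1e-9


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve of one structure."""

    structure: str
    dose_edges: np.ndarray  # Gy
    cumulative_volume: np.ndarray  # fraction of structure receiving >= edge
    total_volume: float  # cc

    def __post_init__(self):
        if self.cumulative_volume[0] != 1.0 or np.any(
            np.diff(self.cumulative_volume) > 1e-12
        ):
            raise ValueError("cumulative DVH must start at 1.0 and be non-increasing")


@dataclass(frozen=True)
class DoseMetricSpec:
    """One DVH metric: V_relative / V_absolute / D_relative / D_absolute_cc."""

    kind: str
    argument: float  # % of prescription, Gy, % of volume, or cc
    prescription: Optional[float] = None  # Gy, required for relative-dose kinds

    def __post_init__(self):
        if self.kind not in ("V_relative", "V_absolute", "D_relative", "D_absolute_cc"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.argument <= 0:
            raise ValueError("metric argument must be positive")
        if self.kind == "V_relative" and not (self.prescription and self.prescription > 0):
            raise ValueError("V_relative needs a positive prescription dose")

    @property
    def label(self) -> str:
        if self.kind == "V_relative":
            return f"V{self.argument:g}%"
        if self.kind == "V_absolute":
            return f"V{self.argument:g}Gy"
        if self.kind == "D_relative":
            return f"D{self.argument:g}%"
        return f"D{self.argument:g}cc"


_METRIC_RE = re.compile(r"^([VD])\s*([\d.]+)\s*(%|Gy|cc)$", re.IGNORECASE)


def parse_metric(text: str, prescription: Optional[float] = None) -> DoseMetricSpec:
    """Parse clinical shorthand like ``V95%``, ``V45Gy``, ``D0.03cc``, ``D10%``."""
    m = _METRIC_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse dose metric {text!r}")
    letter, arg, unit = m.group(1).upper(), float(m.group(2)), m.group(3).lower()
    if letter == "V":
        kind = "V_relative" if unit == "%" else "V_absolute"
        if unit == "cc":
            raise ValueError("Vcc metrics are not supported")
    else:
        kind = {"%": "D_relative", "cc": "D_absolute_cc"}.get(unit)
        if kind is None:
            raise ValueError("DxGy is not a metric; use V or D with %/cc")
    return DoseMetricSpec(kind, arg, prescription)


# ---------------------------------------------------------------------------

def warp_dose(
    dose: DoseGrid,
    dvf: DisplacementField,
    return_outside: bool = False,
):
    """Estimate the treated dose: pull the planned dose through the DVF.

    ``dvf`` must map verification-frame points to planning-frame points
    (i.e. the field from registering fixed = vCBCT against moving = pCBCT;
    use :func:`oartmotion.registration.invert_field` if yours points the other
    way). Trilinear sampling; points landing outside the planned dose extent
    take 0 Gy and are flagged in the optional outside-mask return.
    """
    xs, ys, zs = dvf.grid.coordinate_arrays()
    pts = np.stack([xs, ys, zs], axis=-1) + dvf.vectors
    vals = sample_at_physical(dose.dose, dose.grid, pts, "trilinear", 0.0)
    treated = DoseGrid(dvf.grid, np.clip(vals, 0.0, None))
    if not return_outside:
        return treated
    idx = dose.grid.physical_to_index(pts.reshape(-1, 3)).reshape(*pts.shape)
    hi = np.asarray(dose.grid.size) - 0.5
    outside = np.any((idx < -0.5) | (idx > hi), axis=-1)
    return treated, BinaryMask(dvf.grid, outside)


def compute_dvh(
    dose: DoseGrid,
    mask: BinaryMask,
    bin_width: float = 0.05,
    structure: str = "",
) -> DVHCurve:
    """Cumulative (>= dose) DVH over the mask, volume-weighted."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not mask.grid.same_geometry(dose.grid):
        mask = resample_mask(mask, dose.grid)
    if not mask.values.any():
        raise UndefinedMetricError("empty structure: DVH undefined")
    vals = dose.dose[mask.values]
    top = max(float(vals.max()), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    thr = edges * (1.0 - DOSE_RTOL)
    survival = (vals[np.newaxis, :] >= thr[:, np.newaxis]).mean(axis=1)
    survival[0] = 1.0
    return DVHCurve(
        structure=structure,
        dose_edges=edges,
        cumulative_volume=survival,
        total_volume=mask.volume_cc(),
    )


def dose_metric(dvh: DVHCurve, spec: DoseMetricSpec) -> float:
    """Extract one metric from a DVH with linear interpolation within bins.

    Returns percent volume for V-kind metrics and Gy for D-kind metrics.
    """
    edges, surv = dvh.dose_edges, dvh.cumulative_volume
    if spec.kind in ("V_relative", "V_absolute"):
        d = (
            spec.argument / 100.0 * spec.prescription
            if spec.kind == "V_relative"
            else spec.argument
        )
        if d >= edges[-1]:
            return 0.0
        return 100.0 * float(np.interp(d, edges, surv))
    if spec.kind == "D_absolute_cc":
        if spec.argument > dvh.total_volume * (1 + 1e-9):
            raise UndefinedMetricError(
                f"{spec.label}: structure holds only {dvh.total_volume:.2f} cc"
            )
        q = min(spec.argument / dvh.total_volume, 1.0)
    else:
        q = spec.argument / 100.0
    # smallest dose whose survival has dropped to q: invert the monotone curve
    return float(np.interp(q, surv[::-1], edges[::-1]))


@dataclass
class Goal:
    structure: str
    metric: str  # clinical shorthand, e.g. "V95%" or "D0.03cc"
    cmp: str  # ">=" or "<="
    limit: float
    prescription: Optional[float] = None


@dataclass
class PlanComparison:
    table: pd.DataFrame  # structure, metric, intended, treated, delta, [goal columns]


def compare_plans(
    intended: DoseGrid,
    treated: DoseGrid,
    structures: dict,
    goals: Sequence[Goal],
    bin_width: float = 0.05,
) -> PlanComparison:
    """Intended-vs-treated dose metrics per structure, with goal outcomes.

    ``structures`` maps a name either to one mask (used on both frames) or to
    a ``(planning_mask, verification_mask)`` pair — intended metrics use the
    planning-frame mask, treated metrics the verification-frame mask.
    """
    rows = []
    for goal in goals:
        if goal.structure not in structures:
            raise KeyError(
                f"goal references missing ROI {goal.structure!r}; "
                f"available: {sorted(structures)}"
            )
        entry = structures[goal.structure]
        mask_i, mask_t = entry if isinstance(entry, tuple) else (entry, entry)
        spec = parse_metric(goal.metric, goal.prescription)
        vi = dose_metric(compute_dvh(intended, mask_i, bin_width, goal.structure), spec)
        vt = dose_metric(compute_dvh(treated, mask_t, bin_width, goal.structure), spec)
        row = {
            "structure": goal.structure,
            "metric": spec.label,
            "intended": vi,
            "treated": vt,
            "delta": vt - vi,
        }
        if goal.cmp in (">=", "<="):
            op = (lambda v: v >= goal.limit) if goal.cmp == ">=" else (
                lambda v: v <= goal.limit
            )
            row["limit"] = goal.limit
            row["cmp"] = goal.cmp
            row["intended_pass"] = bool(op(vi))
            row["treated_pass"] = bool(op(vt))
        rows.append(row)
    return PlanComparison(pd.DataFrame(rows))


def sum_course(doses: Sequence[DoseGrid]) -> DoseGrid:
    """Plain per-voxel sum of per-fraction doses on a shared grid."""
    grid = doses[0].grid
    total = np.zeros(grid.size)
    for d in doses:
        if not d.grid.same_geometry(grid):
            raise ValueError("course summation requires a common grid")
        total += d.dose
    return DoseGrid(grid, total)
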