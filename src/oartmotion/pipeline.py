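"""End-to-end analysis pipeline: fraction records -> per-stage CSV reports.

Stages mirror the clinical evaluation chain: geometric contour comparison,
deformable registration, displacement-field motion summary, dose warping with
DVH comparison, and cohort-level longitudinal statistics. Fractions missing
an input for a stage are skipped for that stage with an explicit gap record,
never silently. Re-running over an existing output directory skips stages
whose outputs already exist under an identical configuration hash.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as oio
from .cohort_stats import (
    build_cohort_table,
    fraction_row,
    trend_regression,
    variability_summary,
)
from .contour_metrics import geometric_report
from .deformation import exceedance_table, summarize_deformation
from .dosimetry import Goal, compare_plans, warp_dose
from .geometry import dilate_mask
from .phantom import FractionRecord
from .registration import RegistrationConfig, deformable_register

log = logging.getLogger("oartmotion")


@dataclass
class PipelineConfig:
    thresholds: tuple = (3.0, 5.0, 7.0)
    hd_mode: str = "slice2d"
    dvh_bin_width: float = 0.05
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    goals: Optional[list] = None  # list of Goal; None -> coverage defaults
    prescription_gy: float = 5.0
    ptv_margin_mm: float = 7.0
    seed: int = 0

    def __post_init__(self):
        t = tuple(self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])) or any(x <= 0 for x in t):
            raise ValueError("thresholds must be positive and strictly increasing")
        self.thresholds = t

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def default_goals(prescription: float) -> list[Goal]:
    return [
        Goal("CTV", "V100%", ">=", 95.0, prescription),
        Goal("PTV", "V95%", ">=", 95.0, prescription),
    ]


def _fraction_key(rec: FractionRecord) -> tuple:
    return (rec.patient_id, rec.fraction_index)


class _StageCache:
    """Config-hash-keyed stage markers enabling resumable runs."""

    def __init__(self, out_dir: Path, cfg_hash: str):
        self.path = out_dir / ".stages.json"
        self.cfg_hash = cfg_hash
        self.state = {}
        if self.path.exists():
            self.state = json.loads(self.path.read_text())

    def fresh(self, stage: str, outputs: Sequence[Path]) -> bool:
        return self.state.get(stage) == self.cfg_hash and all(
            p.exists() for p in outputs
        )

    def mark(self, stage: str) -> None:
        self.state[stage] = self.cfg_hash
        self.path.write_text(json.dumps(self.state, indent=1))


def run_pipeline(
    records: Sequence[FractionRecord],
    cfg: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run every stage over the cohort; returns the report bundle as a dict
    of DataFrames (also written as CSV/JSON under ``out_dir``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out, cfg.content_hash())
    timings: dict[str, float] = {}
    gaps: list[dict] = []
    bundle: dict = {}

    def stage(name: str, filename: str, builder) -> pd.DataFrame:
        path = out / filename
        if cache.fresh(name, [path]):
            log.info("stage %s: up to date, skipping", name)
            df = pd.read_csv(path)
            bundle[name] = df
            return df
        t0 = time.perf_counter()
        df = builder()
        df.to_csv(path, index=False)
        cache.mark(name)
        timings[name] = time.perf_counter() - t0
        log.info("stage %s: %d rows in %.1fs", name, len(df), timings[name])
        bundle[name] = df
        return df

    # -- contours ----------------------------------------------------------
    def build_contours() -> pd.DataFrame:
        rows = []
        for rec in records:
            rep = geometric_report(
                rec.bladder_p, rec.bladder_v, rec.t_p, rec.t_v, cfg.hd_mode
            )
            rows.append(
                fraction_row(
                    rec.patient_id, rec.fraction_index, rep,
                    rec.protocol, rec.position,
                )
            )
        return build_cohort_table(rows)

    contours = stage("contours", "contours.csv", build_contours)

    # -- registration + deformation -----------------------------------------
    reg_results: dict[tuple, object] = {}

    def build_registration() -> pd.DataFrame:
        rows = []
        for rec in records:
            res = deformable_register(
                rec.vcbct, rec.pcbct, cfg.registration,
                fixed_mask=rec.bladder_v, moving_mask=rec.bladder_p,
            )
            reg_results[_fraction_key(rec)] = res
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "fraction_index": rec.fraction_index,
                    "validation_dsc": res.validation_dsc,
                    "converged": res.converged,
                }
            )
        return pd.DataFrame(rows)

    registration = stage("registration", "registration.csv", build_registration)

    def build_deformation() -> pd.DataFrame:
        pairs = []
        for rec in records:
            key = _fraction_key(rec)
            if key not in reg_results:  # resumed run: registration was cached
                res = deformable_register(
                    rec.vcbct, rec.pcbct, cfg.registration,
                    fixed_mask=rec.bladder_v, moving_mask=rec.bladder_p,
                )
                reg_results[key] = res
            summ = summarize_deformation(
                reg_results[key].dvf, rec.bladder_v, cfg.thresholds
            )
            labels = {
                "patient_id": rec.patient_id,
                "fraction_index": rec.fraction_index,
                "protocol": rec.protocol,
                "position": rec.position,
            }
            pairs.append((labels, summ))
        per_fraction = pd.concat(
            [s.exceedance.assign(**lab) for lab, s in pairs], ignore_index=True
        )
        cohort = exceedance_table(
            [({"protocol": l["protocol"], "position": l["position"]}, s)
             for l, s in pairs]
        )
        cohort.to_csv(out / "exceedance_cohort.csv", index=False)
        return per_fraction

    stage("deformation", "deformation.csv", build_deformation)

    # -- dosimetry -----------------------------------------------------------
    def build_dosimetry() -> pd.DataFrame:
        goals = cfg.goals or default_goals(cfg.prescription_gy)
        rows = []
        for rec in records:
            if rec.dose_intended is None:
                gaps.append(
                    {
                        "patient_id": rec.patient_id,
                        "fraction_index": rec.fraction_index,
                        "stage": "dosimetry",
                        "reason": "no intended dose for this fraction",
                    }
                )
                continue
            key = _fraction_key(rec)
            dvf = (
                reg_results[key].dvf if key in reg_results else rec.truth_dvf
            )
            if dvf is None:
                gaps.append(
                    {
                        "patient_id": rec.patient_id,
                        "fraction_index": rec.fraction_index,
                        "stage": "dosimetry",
                        "reason": "no displacement field available",
                    }
                )
                continue
            treated = warp_dose(rec.dose_intended, dvf)
            structures = {
                "CTV": (rec.bladder_p, rec.bladder_v),
                "PTV": (
                    rec.target_masks.get("PTV", dilate_mask(rec.bladder_p, cfg.ptv_margin_mm)),
                    dilate_mask(rec.bladder_v, cfg.ptv_margin_mm),
                ),
            }
            comp = compare_plans(
                rec.dose_intended, treated, structures, goals, cfg.dvh_bin_width
            )
            df = comp.table.assign(
                patient_id=rec.patient_id, fraction_index=rec.fraction_index
            )
            rows.append(df)
        if not rows:
            return pd.DataFrame(
                columns=["patient_id", "fraction_index", "structure", "metric",
                         "intended", "treated", "delta"]
            )
        return pd.concat(rows, ignore_index=True)

    stage("dosimetry", "dosimetry.csv", build_dosimetry)

    # -- cohort statistics ---------------------------------------------------
    def build_cohort() -> pd.DataFrame:
        rows = []
        for metric in ("volume_p_cc", "delta_cc", "relative_change_pct",
                       "expansion_rate_cc_min", "hd95_mm"):
            s = variability_summary(contours, metric)
            rows.append(asdict(s))
        return pd.DataFrame(rows)

    stage("cohort", "cohort_summary.csv", build_cohort)

    trends = {}
    for metric in ("relative_change_pct", "hd95_mm"):
        try:
            fit = trend_regression(contours["dt_min"], contours[metric])
            trends[metric] = {
                "slope_per_min": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n,
            }
        except ValueError as exc:
            gaps.append({"stage": "trend", "metric": metric, "reason": str(exc)})
    (out / "trends.json").write_text(json.dumps(trends, indent=1))
    bundle["trends"] = trends

    pd.DataFrame(gaps).to_csv(out / "gaps.csv", index=False)
    run_log = {
        "config_hash": cfg.content_hash(),
        "timestamp": _dt.datetime.now().isoformat(),
        "n_fractions": len(records),
        "stage_seconds": timings,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    bundle["gaps"] = pd.DataFrame(gaps)
    return bundle


# ---------------------------------------------------------------------------
# Manifest loading (explicit CSV instead of DICOM directory walking)
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "patient_id", "fraction_index", "pcbct", "vcbct", "bladder_p", "bladder_v",
    "t_p", "t_v",
)


def load_manifest(path: str | Path) -> list[FractionRecord]:
    """Load fraction records from a manifest CSV.

    Required columns: patient_id, fraction_index, pcbct, vcbct, bladder_p,
    bladder_v (volume/mask file paths) and t_p, t_v (ISO timestamps).
    Optional: dose, dvf, protocol, position. Relative paths resolve against
    the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    root = path.parent
    records = []
    for _, row in df.iterrows():
        def p(col):
            return root / str(row[col])

        rec = FractionRecord(
            patient_id=str(row["patient_id"]),
            fraction_index=int(row["fraction_index"]),
            pcbct=oio.read_scalar(p("pcbct")),
            vcbct=oio.read_scalar(p("vcbct")),
            bladder_p=oio.read_mask(p("bladder_p")),
            bladder_v=oio.read_mask(p("bladder_v")),
            t_p=_dt.datetime.fromisoformat(str(row["t_p"])),
            t_v=_dt.datetime.fromisoformat(str(row["t_v"])),
            protocol=str(row.get("protocol", "")) if "protocol" in df.columns else "",
            position=str(row.get("position", "")) if "position" in df.columns else "",
        )
        if "dose" in df.columns and isinstance(row["dose"], str):
            rec.dose_intended = oio.read_dose(p("dose"))
        if "dvf" in df.columns and isinstance(row["dvf"], str):
            rec.truth_dvf = oio.read_field(p("dvf"))
        records.append(rec)
    return records


def export_cohort(records: Sequence[FractionRecord], out_dir: str | Path) -> Path:
    """Write a cohort to NIfTI files plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.patient_id}_fx{rec.fraction_index:02d}"
        paths = {
            "pcbct": f"{stem}_pcbct.nii.gz",
            "vcbct": f"{stem}_vcbct.nii.gz",
            "bladder_p": f"{stem}_bladder_p.nii.gz",
            "bladder_v": f"{stem}_bladder_v.nii.gz",
        }
        oio.write_scalar(rec.pcbct, out / paths["pcbct"])
        oio.write_scalar(rec.vcbct, out / paths["vcbct"])
        oio.write_mask(rec.bladder_p, out / paths["bladder_p"])
        oio.write_mask(rec.bladder_v, out / paths["bladder_v"])
        row = {
            "patient_id": rec.patient_id,
            "fraction_index": rec.fraction_index,
            **paths,
            "t_p": rec.t_p.isoformat(),
            "t_v": rec.t_v.isoformat(),
            "protocol": rec.protocol,
            "position": rec.position,
            "volume_p_cc": rec.bladder_p.volume_cc(),
            "volume_v_cc": rec.bladder_v.volume_cc(),
        }
        if rec.truth_dvf is not None:
            row["dvf"] = f"{stem}_truth_dvf.mha"
            oio.write_field(rec.truth_dvf, out / row["dvf"])
        if rec.dose_intended is not None:
            row["dose"] = f"{stem}_dose.nii.gz"
            oio.write_scalar(rec.dose_intended, out / row["dose"])
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
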