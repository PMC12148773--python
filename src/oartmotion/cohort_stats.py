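"""Longitudinal cohort statistics for per-fraction bladder metrics.

Works on a tidy per-fraction table (one row per patient x fraction) holding
the geometric and dosimetric metrics. Provides group means with intra- and
inter-patient variability (intra = mean over patients of each patient's
within-course SD; inter = SD of the patient means), pooled ordinary
least-squares time-trend regression with the slope t-test, and weekly box
statistics (median/mean, quartiles, 1.5*IQR whiskers).

Regression pools all fractions, ignoring within-patient correlation — the
conventional simple analysis for this kind of cohort; p-values are reported
raw, with no multiple-testing correction. Treat them descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .contour_metrics import GeometricReport


class DegenerateDesignError(ValueError):
    pass


REQUIRED_COLUMNS = ("patient_id", "fraction_index")


def build_cohort_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble tidy per-fraction rows; adds week_index = ceil(fraction / 5).

    Rows may come from :func:`fraction_row` or any mapping with at least
    patient_id and fraction_index.
    """
    df = pd.DataFrame(list(rows))
    for c in REQUIRED_COLUMNS:
        if c not in df.columns:
            raise ValueError(f"cohort table needs column {c!r}")
    if "week_index" not in df.columns:
        df["week_index"] = np.ceil(df["fraction_index"] / 5).astype(int)
    return df


def fraction_row(
    patient_id: str,
    fraction_index: int,
    report: GeometricReport,
    protocol: str = "",
    position: str = "",
    **extra,
) -> dict:
    row = {
        "patient_id": patient_id,
        "fraction_index": fraction_index,
        "protocol": protocol,
        "position": position,
        "dt_min": report.dt,
        "volume_p_cc": report.volume_p,
        "volume_v_cc": report.volume_v,
        "delta_cc": report.delta_cc,
        "relative_change_pct": report.relative_change,
        "expansion_rate_cc_min": report.expansion_rate,
        "hd95_mm": report.hd95,
        "hd_max_mm": report.hd_max,
        "dsc": report.dsc,
    }
    row.update(extra)
    return row


@dataclass
class VariabilitySummary:
    metric: str
    group_mean: float
    group_sd: float
    intra_patient_sd: float  # mean over patients of within-patient SD
    inter_patient_sd: float  # SD of patient means
    intra_patient_sd_pooled: float  # pooled-variance alternative
    n_patients: int
    n_fractions: int
    intra_defined: bool


def variability_summary(table: pd.DataFrame, metric: str) -> VariabilitySummary:
    """Group mean/SD plus intra- and inter-patient variability of one metric."""
    vals = table[metric].astype(float)
    grouped = table.groupby("patient_id")[metric]
    per_sd = grouped.std(ddof=1)
    per_n = grouped.size()
    means = grouped.mean()
    multi = per_n >= 2
    intra_defined = bool(multi.any()) and len(means) >= 2
    if multi.any():
        intra = float(per_sd[multi].mean())
        pooled_var = float(
            ((per_n[multi] - 1) * per_sd[multi] ** 2).sum() / (per_n[multi] - 1).sum()
        )
        pooled = float(np.sqrt(pooled_var))
    else:
        intra = np.nan
        pooled = np.nan
    return VariabilitySummary(
        metric=metric,
        group_mean=float(vals.mean()),
        group_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        intra_patient_sd=intra,
        inter_patient_sd=float(means.std(ddof=1)) if len(means) > 1 else np.nan,
        intra_patient_sd_pooled=pooled,
        n_patients=int(len(means)),
        n_fractions=int(len(vals)),
        intra_defined=intra_defined,
    )


@dataclass
class TrendFit:
    slope: float  # per minute
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test for slope = 0
    slope_se: float
    conf_int: tuple  # 95% CI for the slope
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def trend_regression(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Pooled OLS of a metric against on-couch time, with the slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateDesignError("need at least 3 finite observations")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in the predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    # a constant response has no variance to explain: R^2 = 0 by convention
    r2 = float(model.rsquared) if np.ptp(y) > 0 else 0.0
    pval = float(model.pvalues[1])
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        p_value=pval if np.isfinite(pval) else 1.0,
        slope_se=float(model.bse[1]),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
        n=int(model.nobs),
    )


def mean_confidence_band(
    fit: TrendFit, x_obs: Sequence[float], x_eval: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """95% confidence band for the mean response of a fitted trend."""
    from scipy import stats

    x_obs = np.asarray(x_obs, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = fit.n
    xbar = x_obs.mean()
    sxx = np.sum((x_obs - xbar) ** 2)
    sigma = fit.slope_se * np.sqrt(sxx)  # residual SE recovered from slope SE
    se_mean = sigma * np.sqrt(1.0 / n + (x_eval - xbar) ** 2 / sxx)
    t = stats.t.ppf(0.975, n - 2)
    yhat = fit.predict(x_eval)
    return yhat - t * se_mean, yhat + t * se_mean


def weekly_boxstats(
    table: pd.DataFrame,
    metric: str,
    strata: Sequence[str] = ("protocol", "position"),
) -> pd.DataFrame:
    """Per-week box statistics: median, mean, Q1/Q3 (linear-interpolation
    quartiles) and whiskers at the most extreme data within 1.5*IQR."""
    strata = [s for s in strata if s in table.columns]
    rows = []
    for keys, grp in table.groupby([*strata, "week_index"], dropna=False):
        vals = grp[metric].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        row = dict(zip([*strata, "week_index"], keys if isinstance(keys, tuple) else (keys,)))
        row.update(
            median=float(med), mean=float(vals.mean()), q1=float(q1), q3=float(q3),
            whisker_low=float(inside.min()), whisker_high=float(inside.max()),
            n=int(vals.size),
        )
        rows.append(row)
    return pd.DataFrame(rows)


# -- optional plotting ------------------------------------------------------

def plot_weekly_boxes(table: pd.DataFrame, metric: str, path, stratum: Optional[str] = "protocol"):
    """Weekly box plots of one metric, optionally split by a stratum column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if stratum is not None and stratum in table.columns:
        groups = [(name, grp) for name, grp in table.groupby(stratum)]
    else:
        groups = [("all", table)]
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4),
                             squeeze=False)
    for ax, (name, grp) in zip(axes[0], groups):
        weeks = sorted(grp["week_index"].unique())
        data = [grp.loc[grp["week_index"] == w, metric].dropna() for w in weeks]
        ax.boxplot(data, tick_labels=[str(w) for w in weeks], whis=1.5, showmeans=True)
        ax.set_title(f"{metric} — {name}")
        ax.set_xlabel("week")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trend(x, y, fit: TrendFit, path, xlabel="on-couch time (min)", ylabel=""):
    """Scatter + fitted line + 95% mean-response confidence band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    xe = np.linspace(np.nanmin(x), np.nanmax(x), 100)
    lo, hi = mean_confidence_band(fit, x, xe)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.6)
    ax.plot(xe, fit.predict(xe), "k-")
    ax.plot(xe, lo, "k--", lw=0.8)
    ax.plot(xe, hi, "k--", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"slope={fit.slope:.3g}/min, R²={fit.r_squared:.2f}, p={fit.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
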