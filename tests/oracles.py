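"""Independent brute-force reference implementations used to validate the
package's metrics. Deliberately naive (explicit loops, direct definitions,
no shared code with the implementation) so agreement is meaningful."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def boundary_points_bruteforce(mask_values: np.ndarray, grid) -> np.ndarray:
    """Face-connected boundary voxel centers in mm, by explicit neighbor checks."""
    pts = []
    nx, ny, nz = mask_values.shape
    for i, j, k in np.argwhere(mask_values):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                pts.append((i, j, k))
                break
            if not mask_values[ii, jj, kk]:
                pts.append((i, j, k))
                break
    return grid.index_to_physical(np.asarray(pts, dtype=float))


def hausdorff_bruteforce(mask_a, mask_b, percentile: float) -> float:
    """Directed boundary-distance percentile via a full distance matrix (3-D)."""
    pa = boundary_points_bruteforce(mask_a.values, mask_a.grid)
    pb = boundary_points_bruteforce(mask_b.values, mask_b.grid)
    d = cdist(pa, pb).min(axis=1)
    return float(np.percentile(d, percentile, method="linear"))


def dice_bruteforce(mask_a, mask_b) -> float:
    inter = 0
    a_count = 0
    b_count = 0
    it = np.nditer(mask_a.values, flags=["multi_index"])
    for va in it:
        vb = mask_b.values[it.multi_index]
        a_count += bool(va)
        b_count += bool(vb)
        inter += bool(va) and bool(vb)
    return 2.0 * inter / (a_count + b_count)


def dvh_bruteforce(dose_values: np.ndarray, mask_values: np.ndarray,
                   edges: np.ndarray) -> np.ndarray:
    """Survival fractions at the given dose edges by direct counting."""
    vals = sorted(dose_values[mask_values])
    n = len(vals)
    out = []
    for e in edges:
        count = sum(1 for v in vals if v >= e * (1 - 1e-9))
        out.append(count / n)
    out[0] = 1.0
    return np.asarray(out)


def dose_metric_bruteforce(dose_values: np.ndarray, mask_values: np.ndarray,
                           voxel_cc: float, kind: str, argument: float,
                           prescription: float | None = None) -> float:
    """Sort-based DVH metrics straight from the voxel doses."""
    vals = np.sort(dose_values[mask_values])[::-1]  # hottest first
    n = len(vals)
    if kind in ("V_relative", "V_absolute"):
        d = argument / 100.0 * prescription if kind == "V_relative" else argument
        return 100.0 * np.count_nonzero(vals >= d * (1 - 1e-9)) / n
    if kind == "D_relative":
        m = max(int(np.ceil(argument / 100.0 * n)), 1)
    elif kind == "D_absolute_cc":
        m = max(int(np.ceil(argument / voxel_cc)), 1)
    else:
        raise ValueError(kind)
    return float(vals[min(m, n) - 1])


def ols_bruteforce(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple-regression normal equations with the classical slope t-test."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sse = np.sum(resid**2)
    sst = np.sum((y - ybar) ** 2)
    sigma2 = sse / (n - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    t = slope / se_slope
    p = 2 * stats.t.sf(abs(t), n - 2)
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": 1 - sse / sst if sst > 0 else 0.0,
        "p_value": p,
        "slope_se": se_slope,
    }


def jacobian_analytic_oracle(field_fn, points: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """det(I + du/dx) of an analytic field by tiny-step central differences."""
    out = np.empty(points.shape[0])
    for idx, p in enumerate(points):
        J = np.eye(3)
        for a in range(3):
            e = np.zeros(3)
            e[a] = h
            J[:, a] += (field_fn(p + e) - field_fn(p - e)) / (2 * h)
        out[idx] = np.linalg.det(J)
    return out
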