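"""Calibration factors, activity quantification and cohort statistics.

The calibration factor (CF, cps/MBq) is the slope of an ordinary
least-squares regression of reconstructed count rate on administered
activity, fitted either from whole field-of-view counts (method 1) or from
liver-VOI counts only (method 2).  Dividing a count-rate image by the CF
converts it to activity (MBq); the signed percent error against the
administered activity is

    %Error = (true − estimated) / true × 100.

Also provided: Pearson correlation, a paired-t summary, and Grubbs' single
outlier test — the statistics used when comparing planning (MAA) and
post-therapy (Y-90) studies across a cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imgcore import UnitsError, VoiMask, VoxelGrid, require_units, voi_stats

__all__ = [
    "CalibrationModel",
    "ActivityEstimate",
    "total_counts",
    "fit_calibration",
    "apply_cf",
    "estimate_activity",
    "percent_error",
    "round_half_away",
    "error_summary",
    "pearson_r",
    "paired_t_summary",
    "paired_t_from_samples",
    "grubbs_max_outlier",
]


@dataclass
class CalibrationModel:
    """OLS calibration of counts (cps) on administered activity (MBq)."""

    method: str  # "whole_fov" | "liver_voi"
    slope: float  # the CF, cps/MBq
    intercept: float  # cps, diagnostic only
    r_squared: float
    slope_se: float
    slope_ci95: tuple[float, float]
    n: int
    valid: bool = True  # False when the fit is degenerate (slope <= 0)


@dataclass
class ActivityEstimate:
    total_MBq: float
    source: str  # "whole_fov" | "voi"
    cf_used: float
    percent_error: float | None = None  # vs administered, when known


def total_counts(img: VoxelGrid, mask: VoiMask | None = None) -> float:
    """Total count rate over a VOI, or over the whole FOV when mask is None."""
    require_units(img, "cps")
    if mask is None:
        return float(img.data.sum())
    return voi_stats(img, mask)["total"]


def fit_calibration(
    activities_MBq,
    counts_cps,
    method: str = "liver_voi",
    through_origin: bool = False,
) -> CalibrationModel:
    """Fit the calibration line counts = CF · activity (+ intercept).

    Free intercept by default; the CF is the slope only.  The 95% CI is
    slope ± t(0.975, n−2) · SE(slope) (n−1 df when through the origin).
    """
    x = np.asarray(activities_MBq, dtype=np.float64)
    y = np.asarray(counts_cps, dtype=np.float64)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 (activity, counts) pairs")
    if np.ptp(x) == 0:
        raise ValueError("activities have zero variance")
    if through_origin:
        slope = float(x @ y / (x @ x))
        resid = y - slope * x
        dof = x.size - 1
        mse = float(resid @ resid) / dof if dof > 0 else 0.0
        se = math.sqrt(mse / float(x @ x))
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        intercept = 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, se = float(res.slope), float(res.intercept), float(res.stderr)
        r2 = float(res.rvalue) ** 2
        dof = x.size - 2
    tcrit = float(stats.t.ppf(0.975, dof)) if dof > 0 else float("inf")
    ci = (slope - tcrit * se, slope + tcrit * se)
    return CalibrationModel(
        method=method,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_se=se,
        slope_ci95=ci,
        n=int(x.size),
        valid=slope > 0,
    )


def apply_cf(img: VoxelGrid, cf: float) -> VoxelGrid:
    """Convert a count-rate image to activity by voxelwise division by the CF."""
    require_units(img, "cps")
    if cf <= 0:
        raise ValueError("calibration factor must be > 0")
    return img.with_data(img.data / cf, units="MBq")


def estimate_activity(
    img: VoxelGrid,
    cf: float,
    mask: VoiMask | None = None,
    administered_MBq: float | None = None,
) -> ActivityEstimate:
    """Total activity in a VOI (or whole FOV) from a cps image and a CF."""
    counts = total_counts(img, mask)
    total = counts / cf
    err = percent_error(administered_MBq, total) if administered_MBq else None
    return ActivityEstimate(
        total_MBq=total,
        source="voi" if mask is not None else "whole_fov",
        cf_used=cf,
        percent_error=err,
    )


def percent_error(true_MBq: float, estimated_MBq: float) -> float:
    """Signed percent error (true − estimated) / true × 100."""
    if true_MBq == 0:
        raise ZeroDivisionError("true activity is zero")
    return (true_MBq - estimated_MBq) / true_MBq * 100.0


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report-table style)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def error_summary(errors) -> dict[str, float]:
    """Arithmetic mean and sample (n−1) SD of a sequence of percent errors."""
    e = np.asarray(errors, dtype=np.float64)
    if e.size < 2:
        raise ValueError("need at least 2 errors")
    return {"mean": float(e.mean()), "sd": float(e.std(ddof=1))}


def pearson_r(x, y) -> dict[str, float]:
    """Product-moment correlation with its two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant sequence has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def paired_t_summary(mean_diff: float, sd_diff: float, n: int) -> dict[str, float]:
    """Paired t statistic from the difference summary: t = d̄ / (s_d/√n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff == 0:
        if mean_diff == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0}
        raise ZeroDivisionError("zero SD with nonzero mean difference (infinite t)")
    t = mean_diff / (sd_diff / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return {"t": t, "df": df, "p": p}


def paired_t_from_samples(a, b) -> dict[str, float]:
    """Paired t test from the two raw samples; reduces to the summary form."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    return paired_t_summary(float(d.mean()), float(d.std(ddof=1)), d.size)


def grubbs_max_outlier(x) -> dict[str, float]:
    """Grubbs' test for the single most extreme value.

    G = max|x_i − mean| / s (sample SD); the two-sided p comes from the
    standard t-based relation for the Grubbs critical value.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx]) / s
    # invert G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) for the p-value
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        tval = math.sqrt(n * (n - 2) * g * g / denom)
        p = min(1.0, 2.0 * n * float(stats.t.sf(tval, n - 2)))
    return {"G": g, "index": idx, "p": p}
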