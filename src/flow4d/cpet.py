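"""Cardiopulmonary exercise test metrics, imputation and risk grading.

Peak VO2 is the highest 10-s averaged exercise sample; the VE/VCO2 slope
is the OLS slope of minute ventilation on CO2 output from the start of
exercise to the peak-VO2 sample. Patients unable to complete CPET receive
the conventional default values (peak VO2 14 ml/kg/min, 46 % predicted,
VE/VCO2 slope 45). Stratification thresholds: peak VO2 <= 15 ml/kg/min is
abnormal; % predicted <= 65 and/or slope >= 36 flags intermediate/high
exercise risk (boundary values inclusive). Composite risk is the mean of
per-variable 1-3 grades rounded to the nearest integer (half-points round
up, toward higher risk).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import CPETSeries

__all__ = [
    "CPETSummary", "DEFAULT_IMPUTED", "peak_vo2", "ve_vco2_slope",
    "percent_predicted", "impute_incomplete", "stratify", "overall_risk",
    "summarize_cpet", "bin_breaths",
]

#: Default values recorded for patients who could not complete full CPET:
#: (peak VO2 ml/kg/min, % predicted peak VO2, VE/VCO2 slope).
DEFAULT_IMPUTED = (14.0, 46.0, 45.0)

PEAK_VO2_ABNORMAL = 15.0     # ml/kg/min, abnormal if <=
PCT_PRED_RISK = 65.0         # %, at-risk if <=
VEVCO2_RISK = 36.0           # at-risk if >=


@dataclass
class CPETSummary:
    peak_vo2: float
    predicted_vo2: float | None
    pct_predicted: float
    vevco2_slope: float
    imputed: bool = False
    peak_vo2_class: str | None = None       # 'preserved' | 'abnormal'
    exercise_risk_flag: bool | None = None


def bin_breaths(time_s, vo2, bin_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Average raw breath-by-breath samples into consecutive 10-s bins."""
    time_s = np.asarray(time_s, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    edges = np.arange(time_s.min(), time_s.max() + bin_s, bin_s)
    idx = np.digitize(time_s, edges) - 1
    centers, means = [], []
    for b in range(idx.max() + 1):
        sel = idx == b
        if np.any(sel):
            centers.append(edges[b] + bin_s / 2)
            means.append(vo2[sel].mean())
    return np.array(centers), np.array(means)


def peak_vo2(series: CPETSeries) -> float:
    """Highest 10-s averaged VO2 sample during exercise, ml/kg/min."""
    sel = series.phase == "exercise"
    if not np.any(sel):
        raise ValueError("no exercise-phase samples")
    return float(series.vo2[sel].max())


def ve_vco2_slope(series: CPETSeries) -> float:
    """OLS slope of VE on VCO2 from exercise start to the peak-VO2 sample.

    The interval ends at the first sample achieving peak VO2.
    """
    ex = np.flatnonzero(series.phase == "exercise")
    if len(ex) == 0:
        raise ValueError("no exercise-phase samples")
    peak_idx = ex[int(np.argmax(series.vo2[ex]))]
    sel = ex[ex <= peak_idx]
    if len(sel) < 3:
        raise ValueError("need at least 3 samples from exercise start to peak")
    vco2 = series.vco2[sel]
    if np.ptp(vco2) == 0:
        raise ValueError("zero variance in VCO2 over the slope interval")
    res = stats.linregress(vco2, series.ve[sel])
    return float(res.slope)


def percent_predicted(peak: float, predicted: float) -> float:
    """Peak VO2 indexed against the normative predicted value, %."""
    if predicted <= 0:
        raise ValueError("predicted VO2 must be positive")
    return 100.0 * peak / predicted


def impute_incomplete() -> CPETSummary:
    """Default summary for a subject who could not complete CPET."""
    pv, pct, slope = DEFAULT_IMPUTED
    return stratify(CPETSummary(
        peak_vo2=pv, predicted_vo2=None, pct_predicted=pct,
        vevco2_slope=slope, imputed=True,
    ))


def stratify(summary: CPETSummary) -> CPETSummary:
    """Attach the peak-VO2 class and the exercise risk flag.

    Abnormal peak VO2: <= 15 ml/kg/min. Exercise risk: % predicted <= 65
    and/or VE/VCO2 slope >= 36 (both boundaries inclusive).
    """
    summary.peak_vo2_class = (
        "abnormal" if summary.peak_vo2 <= PEAK_VO2_ABNORMAL else "preserved"
    )
    summary.exercise_risk_flag = bool(
        summary.pct_predicted <= PCT_PRED_RISK or summary.vevco2_slope >= VEVCO2_RISK
    )
    return summary


def summarize_cpet(series: CPETSeries, predicted: float) -> CPETSummary:
    """Peak VO2, % predicted and VE/VCO2 slope with strata for one test."""
    pv = peak_vo2(series)
    return stratify(CPETSummary(
        peak_vo2=pv,
        predicted_vo2=predicted,
        pct_predicted=percent_predicted(pv, predicted),
        vevco2_slope=ve_vco2_slope(series),
        imputed=False,
    ))


def overall_risk(grades) -> int:
    """Composite risk grade: mean of per-variable grades, rounded to the
    nearest integer with half-points rounding up (toward higher risk)."""
    grades = list(grades)
    if len(grades) == 0:
        raise ValueError("need at least one grade")
    if any(g not in (1, 2, 3) for g in grades):
        raise ValueError("grades must be in {1, 2, 3}")
    return int(math.floor(sum(grades) / len(grades) + 0.5))
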