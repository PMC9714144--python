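"""Cine-CMR scalar metrics.

Remodelling index (RVEDV/LVEDV) and its adverse cutoff (control mean + 3 SD),
ejection fraction, TAPSE, the inter-ventricular synchrony index, planimetered
chamber area, end-systolic global longitudinal strain, and pulmonary-artery
relative area change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .data_model import ContourPolygon, LandmarkCurves

__all__ = [
    "RemodellingAssessment", "remodelling_index", "adverse_cutoff",
    "assess_remodelling", "ejection_fraction", "tapse", "synchrony_index",
    "polygon_area", "gls_at_es", "pa_relative_area_change",
]


@dataclass
class RemodellingAssessment:
    rvedv: float
    lvedv: float
    index: float
    control_mean: float
    control_sd: float
    cutoff: float
    adverse: bool


def remodelling_index(rvedv: float, lvedv: float) -> float:
    """RVEDV/LVEDV ratio (volumes in ml, or both indexed to BSA)."""
    if rvedv <= 0 or lvedv <= 0:
        raise ValueError("ventricular volumes must be positive")
    return rvedv / lvedv


def adverse_cutoff(control_indices, ndigits: int | None = 2) -> float:
    """Adverse-remodelling cutoff: control mean + 3 x sample SD.

    Sample SD uses the n-1 denominator. ``ndigits`` rounds the reported
    cutoff (2 decimals by convention); pass None for the raw value.
    """
    vals = np.asarray(control_indices, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 control values")
    cutoff = float(vals.mean() + 3.0 * vals.std(ddof=1))
    return round(cutoff, ndigits) if ndigits is not None else cutoff


def cutoff_from_summary(mean: float, sd: float, ndigits: int | None = 2) -> float:
    """Cutoff from published control summary statistics (mean + 3 SD)."""
    cutoff = mean + 3.0 * sd
    return round(cutoff, ndigits) if ndigits is not None else cutoff


def assess_remodelling(rvedv: float, lvedv: float,
                       control_mean: float, control_sd: float) -> RemodellingAssessment:
    idx = remodelling_index(rvedv, lvedv)
    cut = cutoff_from_summary(control_mean, control_sd)
    return RemodellingAssessment(
        rvedv=rvedv, lvedv=lvedv, index=idx,
        control_mean=control_mean, control_sd=control_sd,
        cutoff=cut, adverse=idx > cut,
    )


def ejection_fraction(edv: float, esv: float) -> float:
    """EF in %: 100 x (EDV - ESV)/EDV."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    if esv < 0:
        raise ValueError("ESV must be non-negative")
    return 100.0 * (edv - esv) / edv


def tapse(displacement_mm: np.ndarray, systole_frames) -> float:
    """Tricuspid annular plane systolic excursion, mm.

    Maximum displacement of the lateral tricuspid insertion within
    ventricular systole (displacement is referenced to frame 0).
    """
    disp = np.asarray(displacement_mm, dtype=float)
    frames = np.asarray(systole_frames, dtype=int)
    if len(frames) == 0:
        raise ValueError("empty systolic interval")
    if frames.min() < 0 or frames.max() >= len(disp):
        raise ValueError("systolic frames out of range")
    return float(disp[frames].max())


def synchrony_index(mitral_lateral: np.ndarray, tricuspid_lateral: np.ndarray,
                    frame_interval: float, signed: bool = False) -> float:
    """Inter-ventricular synchrony index, ms.

    Time difference to maximal displacement between the lateral tricuspid
    (RV) and lateral mitral (LV) insertions; earliest frame on ties.
    Absolute by default; ``signed=True`` reports RV minus LV.
    """
    mv = np.asarray(mitral_lateral, dtype=float)
    tv = np.asarray(tricuspid_lateral, dtype=float)
    if len(mv) != len(tv):
        raise ValueError("curves must have equal length")
    diff = (int(np.argmax(tv)) - int(np.argmax(mv))) * frame_interval
    return diff if signed else abs(diff)


def synchrony_from_landmarks(lm: LandmarkCurves, signed: bool = False) -> float:
    return synchrony_index(lm.mitral_lateral, lm.tricuspid_lateral,
                           lm.frame_interval, signed=signed)


def polygon_area(contour: ContourPolygon) -> float:
    """Planimetered area of a chamber contour in cm^2 (shoelace on mm vertices)."""
    poly = Polygon(contour.vertices)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("self-intersecting contour polygon")
    return poly.area / 100.0  # mm^2 -> cm^2


def gls_at_es(strain_curve: np.ndarray, es_frame: int) -> float:
    """Global longitudinal strain at end-systole, % (input sign convention kept)."""
    strain = np.asarray(strain_curve, dtype=float)
    if not (0 <= es_frame < len(strain)):
        raise ValueError("ES frame out of range")
    return float(strain[es_frame])


def pa_relative_area_change(areas_cm2: np.ndarray) -> float:
    """Pulmonary-artery relative area change: 100% x (max - min)/min."""
    areas = np.asarray(areas_cm2, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("all PA areas must be positive")
    return 100.0 * (areas.max() - areas.min()) / areas.min()
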