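"""Phasic blood kinetic energy of the ventricular blood pool.

Per frame, KE(t) = sum over labelled voxels of 1/2 * rho * V_voxel * |v|^2,
reported in microjoules, and KEI_EDV = KE / EDV in uJ/ml. The phasic
summaries are the peak systolic, average systolic and peak E-wave KEI_EDV.
Note the unit identity 1 J/m^3 = 1 uJ/ml: for a uniform-speed pool whose
volume equals EDV, KEI_EDV is numerically 1/2 * rho * |v|^2 in J/m^3.

Blood density defaults to 1060 kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import PhaseMask4D, VelocityField4D

__all__ = ["KECurve", "ke_curve", "kei_edv", "phase_landmarks",
           "extract_phasic", "compute_ke", "RHO_BLOOD"]

RHO_BLOOD = 1060.0  # kg/m^3


@dataclass
class KECurve:
    """Per-frame KE (uJ) and KEI_EDV (uJ/ml) with phasic landmarks."""

    ke_uj: np.ndarray
    kei_edv_uj_ml: np.ndarray
    ed_frame: int
    es_frame: int
    e_wave_window: np.ndarray
    peak_systolic: float
    average_systolic: float
    peak_e_wave: float

    def summary(self) -> dict[str, float]:
        return {
            "peak_systolic": self.peak_systolic,
            "average_systolic": self.average_systolic,
            "peak_e_wave": self.peak_e_wave,
        }


def ke_curve(fld: VelocityField4D, mask: PhaseMask4D, ventricle: int,
             rho: float = RHO_BLOOD) -> np.ndarray:
    """Kinetic energy of one ventricle's blood pool per frame, in uJ."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    mask.check_paired(fld)
    voxel_m3 = float(np.prod(fld.voxel_size)) * 1e-9  # mm^3 -> m^3
    speed2 = np.sum((fld.velocity * 0.01) ** 2, axis=-1)  # (cm/s -> m/s)^2
    sel = mask.labels == ventricle
    ke_j = 0.5 * rho * voxel_m3 * np.sum(speed2 * sel, axis=(0, 1, 2))
    return ke_j * 1e6


def kei_edv(ke_uj: np.ndarray, edv_ml: float) -> np.ndarray:
    """EDV-normalized kinetic energy, uJ/ml."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    return np.asarray(ke_uj, dtype=float) / edv_ml


def phase_landmarks(volume_curve: np.ndarray) -> tuple[int, int, np.ndarray]:
    """Locate ED, ES and the E-wave search window on a volume curve.

    ED = argmax volume, ES = argmin (earliest frame on ties). The E-wave
    window is the first half of diastole: frames ``(ES, ES + ceil(n_dia/2)]``
    with periodic wrap, which excludes the late-diastolic A-wave by
    construction.
    """
    vol = np.asarray(volume_curve, dtype=float)
    n = len(vol)
    if n < 2 or np.all(vol == vol[0]):
        raise ValueError("volume curve must be non-constant")
    ed = int(np.argmax(vol))
    es = int(np.argmin(vol))
    n_dia = (ed - es) % n
    if n_dia == 0:
        raise ValueError("degenerate volume curve: ED frame equals ES frame")
    half = int(np.ceil(n_dia / 2))
    window = (es + 1 + np.arange(half)) % n
    return ed, es, window


def extract_phasic(kei: np.ndarray, ed_frame: int, es_frame: int,
                   e_wave_window: np.ndarray) -> tuple[float, float, float]:
    """Peak systolic, average systolic and peak E-wave KEI_EDV.

    Systole is the closed frame interval [ED, ES] (with wrap); the peak is
    the maximum and the average the arithmetic mean over those frames.
    """
    kei = np.asarray(kei, dtype=float)
    n = len(kei)
    n_sys = (es_frame - ed_frame) % n
    sys_frames = (ed_frame + np.arange(n_sys + 1)) % n
    window = np.asarray(e_wave_window, dtype=int)
    if len(window) == 0:
        raise ValueError("empty E-wave window")
    peak_sys = float(kei[sys_frames].max())
    avg_sys = float(kei[sys_frames].mean())
    peak_e = float(kei[window].max())
    return peak_sys, avg_sys, peak_e


def compute_ke(fld: VelocityField4D, mask: PhaseMask4D, ventricle: int,
               rho: float = RHO_BLOOD,
               ed_frame: int | None = None,
               es_frame: int | None = None) -> KECurve:
    """Full KE analysis for one ventricle.

    ED/ES frames come from the volume curve unless declared (static-mask
    phantoms declare them); the E-wave window is always the first half of
    the resulting diastole.
    """
    ke = ke_curve(fld, mask, ventricle, rho=rho)
    if ed_frame is None or es_frame is None:
        ed, es, window = phase_landmarks(mask.volume_curve(ventricle))
        ed_frame = ed if ed_frame is None else ed_frame
        es_frame = es if es_frame is None else es_frame
    n = fld.n_frames
    n_dia = (ed_frame - es_frame) % n
    if n_dia == 0:
        raise ValueError("degenerate phase anchors: ED frame equals ES frame")
    window = (es_frame + 1 + np.arange(int(np.ceil(n_dia / 2)))) % n
    edv = mask.edv(ventricle)
    kei = kei_edv(ke, edv)
    peak_sys, avg_sys, peak_e = extract_phasic(kei, ed_frame, es_frame, window)
    return KECurve(
        ke_uj=ke, kei_edv_uj_ml=kei,
        ed_frame=ed_frame, es_frame=es_frame, e_wave_window=window,
        peak_systolic=peak_sys, average_systolic=avg_sys, peak_e_wave=peak_e,
    )
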