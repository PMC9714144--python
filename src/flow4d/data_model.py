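"""Domain types and file I/O for 4D flow CMR analysis.

Container types for the time-resolved velocity field, the per-phase
ventricular segmentation, cine-derived landmark/contour curves,
breath-by-breath (10-s averaged) CPET series, and the per-subject cohort
table, together with readers/writers for their on-disk formats (NIfTI for
volumetric data, CSV for tabular data, a JSON sidecar for acquisition
metadata).

Conventions
-----------
* Velocities are stored in cm/s (phase-contrast convention); kinetic-energy
  code converts to SI at the point of use.
* The grid is voxel-centered: voxel index ``(i, j, k)`` sits at physical
  position ``(i*dx, j*dy, k*dz)`` in mm, 0-based.
* The cardiac cycle is periodic: frame ``n_frames`` wraps to frame 0.
* Mask labels: 0 = background, 1 = LV, 2 = RV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LV",
    "RV",
    "VelocityField4D",
    "PhaseMask4D",
    "LandmarkCurves",
    "ContourPolygon",
    "CPETSeries",
    "CohortTable",
    "read_velocity_field",
    "write_velocity_field",
    "read_masks",
    "write_masks",
    "read_landmark_curves",
    "write_landmark_curves",
    "read_contours",
    "write_contours",
    "read_cpet_series",
    "write_cpet_series",
    "read_cohort",
    "write_cohort",
]

LV = 1
RV = 2
_KNOWN_LABELS = {0, LV, RV}

#: Mandatory columns of the cohort CSV schema. Unknown extra columns are
#: preserved untouched on read and write.
COHORT_MANDATORY = ["id", "group"]

#: Numeric cohort columns recognised by the pipeline (all optional).
COHORT_NUMERIC = [
    "age", "bsa",
    "rv_direct", "rv_retained", "rv_delayed", "rv_residual",
    "lv_direct", "lv_retained", "lv_delayed", "lv_residual",
    "ffr", "ke_discordance",
    "rv_peak_sys_keiedv", "rv_avg_sys_keiedv", "rv_peak_e_keiedv",
    "lv_peak_sys_keiedv", "lv_avg_sys_keiedv", "lv_peak_e_keiedv",
    "rvedv_i", "rvesv_i", "lvedv_i", "lvesv_i", "rvef", "lvef",
    "remodelling_index", "tapse", "rv_gls", "ra_area", "pa_rac",
    "peak_vo2", "pct_pred_vo2", "vevco2_slope",
    "risk_grade", "reveal_score",
]


class DataModelError(ValueError):
    """Raised when an input violates a data-model contract."""


# ---------------------------------------------------------------------------
# Volumetric types
# ---------------------------------------------------------------------------

@dataclass
class VelocityField4D:
    """Sampled blood-velocity field v(x, t) over one cardiac cycle.

    Parameters
    ----------
    velocity : ndarray, shape (X, Y, Z, T, 3)
        Velocity components in cm/s.
    voxel_size : 3-sequence of float
        Voxel spacing in mm.
    frame_interval : float
        Temporal resolution in ms; the cycle is periodic with duration
        ``n_frames * frame_interval``.
    venc : float
        Velocity-encoding limit of the acquisition in cm/s (metadata).
    """

    velocity: np.ndarray
    voxel_size: np.ndarray
    frame_interval: float
    venc: float = 150.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise DataModelError(
                f"velocity must have shape (X, Y, Z, T, 3), got {self.velocity.shape}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise DataModelError("voxel_size must be 3 positive lengths in mm")
        if self.n_frames < 2:
            raise DataModelError("need at least 2 cardiac phases")
        if self.frame_interval <= 0:
            raise DataModelError("frame_interval must be positive")
        bad = np.count_nonzero(~np.isfinite(self.velocity))
        if bad:
            raise DataModelError(f"velocity contains {bad} non-finite voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[3]

    @property
    def cycle_duration(self) -> float:
        """Cardiac cycle length in ms."""
        return self.n_frames * self.frame_interval

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PhaseMask4D:
    """Per-phase ventricular label map paired with a :class:`VelocityField4D`.

    ``labels`` holds 0/1/2 (background/LV/RV) per voxel per frame. Volume
    curves and EDV/ESV derive from exact voxel counts times voxel volume.
    """

    labels: np.ndarray
    voxel_size: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise DataModelError(
                f"labels must have shape (X, Y, Z, T), got {self.labels.shape}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        unknown = sorted(set(np.unique(self.labels).tolist()) - _KNOWN_LABELS)
        if unknown:
            raise DataModelError(f"unknown label values: {unknown}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0  # mm^3 -> ml

    def volume_curve(self, ventricle: int) -> np.ndarray:
        """Blood-pool volume in ml per frame for one ventricle label."""
        counts = np.count_nonzero(
            self.labels.reshape(-1, self.n_frames) == ventricle, axis=0
        )
        if np.any(counts == 0):
            empty = np.flatnonzero(counts == 0)
            raise DataModelError(
                f"ventricle label {ventricle} empty at frames {empty.tolist()}"
            )
        return counts * self.voxel_volume_ml

    def edv(self, ventricle: int) -> float:
        return float(self.volume_curve(ventricle).max())

    def esv(self, ventricle: int) -> float:
        return float(self.volume_curve(ventricle).min())

    def check_paired(self, fld: VelocityField4D) -> None:
        if self.grid_shape != fld.grid_shape or self.n_frames != fld.n_frames:
            raise DataModelError(
                f"mask grid {self.grid_shape}x{self.n_frames} does not match "
                f"velocity grid {fld.grid_shape}x{fld.n_frames}"
            )


# ---------------------------------------------------------------------------
# Cine / CPET tabular types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkCurves:
    """Feature-tracked valve-insertion displacement curves from cine CMR.

    Displacements are magnitudes of motion toward the apex reference, in mm,
    zero at frame 0. ``strain`` optionally carries the global longitudinal
    strain curve in %.
    """

    time_ms: np.ndarray
    tricuspid_lateral: np.ndarray
    tricuspid_medial: np.ndarray
    mitral_lateral: np.ndarray
    strain: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [self.time_ms, self.tricuspid_lateral, self.tricuspid_medial,
                  self.mitral_lateral]
        if self.strain is not None:
            arrays.append(self.strain)
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise DataModelError("all landmark curves must share one length")
        for name in ("tricuspid_lateral", "tricuspid_medial", "mitral_lateral"):
            if abs(float(getattr(self, name)[0])) > 1e-9:
                raise DataModelError(f"{name} displacement must be 0 at frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.time_ms)

    @property
    def frame_interval(self) -> float:
        return float(np.diff(self.time_ms).mean())


@dataclass
class ContourPolygon:
    """Planar chamber contour (e.g. planimetered RA) at one cine frame."""

    vertices: np.ndarray  # (n, 2) in mm
    frame: int = 0
    chamber: str = "RA"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise DataModelError("vertices must be an (n, 2) array in mm")
        if len(self.vertices) < 3:
            raise DataModelError("polygon needs at least 3 vertices")


@dataclass
class CPETSeries:
    """10-s averaged breath-by-breath gas exchange series.

    ``phase`` flags each sample as 'rest', 'exercise' or 'recovery'.
    """

    time_s: np.ndarray
    ve: np.ndarray          # L/min
    vo2: np.ndarray         # ml/kg/min
    vco2: np.ndarray        # L/min
    phase: np.ndarray       # str flags

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ve = np.asarray(self.ve, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.time_s)
        if any(len(a) != n for a in (self.ve, self.vo2, self.vco2, self.phase)):
            raise DataModelError("CPET columns must share one length")
        if np.any(np.diff(self.time_s) <= 0):
            raise DataModelError("CPET time must be strictly increasing")
        if np.any(self.ve < 0) or np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise DataModelError("gas-exchange values must be non-negative")
        bad = set(np.unique(self.phase)) - {"rest", "exercise", "recovery"}
        if bad:
            raise DataModelError(f"unknown CPET phase flags: {sorted(bad)}")


class CohortTable:
    """One row per subject; thin typed wrapper around a pandas DataFrame."""

    def __init__(self, df: pd.DataFrame):
        for col in COHORT_MANDATORY:
            if col not in df.columns:
                raise DataModelError(f"cohort table missing mandatory column '{col}'")
        df = df.copy()
        df["group"] = df["group"].astype(str).str.strip().apply(_normalize_group)
        for col in COHORT_NUMERIC:
            if col in df.columns:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
                if bad.any():
                    raise DataModelError(
                        f"non-numeric cell(s) in numeric column '{col}': "
                        f"rows {list(df.index[bad])}"
                    )
                df[col] = coerced
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def groups(self) -> pd.Series:
        return self.df["group"].value_counts()

    def subset(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == _normalize_group(group)]


def _normalize_group(value: str) -> str:
    v = value.strip().lower()
    if v in {"pah", "patient", "case"}:
        return "PAH"
    if v in {"control", "ctrl", "healthy", "hc"}:
        return "control"
    raise DataModelError(f"unknown group value '{value}'")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _component_paths(stem: str | Path) -> tuple[list[Path], Path]:
    stem = Path(stem)
    comps = [stem.with_name(stem.name + s) for s in ("_vx.nii.gz", "_vy.nii.gz", "_vz.nii.gz")]
    return comps, stem.with_name(stem.name + "_meta.json")


def write_velocity_field(fld: VelocityField4D, stem: str | Path) -> None:
    """Write a field as three 4D NIfTI component volumes plus a JSON sidecar."""
    comps, meta_path = _component_paths(stem)
    affine = fld.affine
    if affine is None:
        affine = np.diag([*fld.voxel_size, 1.0])
    for i, path in enumerate(comps):
        nib.save(nib.Nifti1Image(fld.velocity[..., i], affine), str(path))
    meta = {
        "voxel_size_mm": list(map(float, fld.voxel_size)),
        "frame_interval_ms": float(fld.frame_interval),
        "venc_cms": float(fld.venc),
    }
    meta_path.write_text(json.dumps(meta, indent=2))


def read_velocity_field(stem: str | Path) -> VelocityField4D:
    """Read three NIfTI component volumes + sidecar into a :class:`VelocityField4D`.

    The three volumes must share shape (X, Y, Z, T); the sidecar supplies
    ``voxel_size_mm``, ``frame_interval_ms`` and ``venc_cms``. The NIfTI
    affine of the first component is recorded for provenance.
    """
    comps, meta_path = _component_paths(stem)
    if not meta_path.exists():
        raise DataModelError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("voxel_size_mm", "frame_interval_ms", "venc_cms"):
        if key not in meta:
            raise DataModelError(f"metadata sidecar missing key '{key}'")
    arrays, affine = [], None
    for path in comps:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if affine is None:
            affine = img.affine
        arrays.append(data)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise DataModelError(f"component shape mismatch: {sorted(shapes)}")
    if arrays[0].ndim != 4:
        raise DataModelError("component volumes must be 4D (X, Y, Z, T)")
    if len({a.shape[3] for a in arrays}) != 1:
        raise DataModelError("frame count mismatch between components")
    velocity = np.stack(arrays, axis=-1)
    return VelocityField4D(
        velocity=velocity,
        voxel_size=np.asarray(meta["voxel_size_mm"], dtype=float),
        frame_interval=float(meta["frame_interval_ms"]),
        venc=float(meta["venc_cms"]),
        affine=affine,
    )


def write_masks(mask: PhaseMask4D, path: str | Path) -> None:
    affine = np.diag([*mask.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), affine), str(path))


def read_masks(path: str | Path, voxel_size=None, frame_interval: float = 1.0) -> PhaseMask4D:
    """Read a 4D label NIfTI (0=background, 1=LV, 2=RV) into a :class:`PhaseMask4D`."""
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    if voxel_size is None:
        voxel_size = np.abs(np.diag(img.affine)[:3])
    return PhaseMask4D(labels=labels, voxel_size=voxel_size, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_landmark_curves(lm: LandmarkCurves, path: str | Path) -> None:
    cols = {
        "time_ms": lm.time_ms,
        "tricuspid_lateral_mm": lm.tricuspid_lateral,
        "tricuspid_medial_mm": lm.tricuspid_medial,
        "mitral_lateral_mm": lm.mitral_lateral,
    }
    if lm.strain is not None:
        cols["strain_pct"] = lm.strain
    pd.DataFrame(cols).to_csv(path, index=False)


def read_landmark_curves(path: str | Path) -> LandmarkCurves:
    df = pd.read_csv(path)
    return LandmarkCurves(
        time_ms=df["time_ms"].to_numpy(float),
        tricuspid_lateral=df["tricuspid_lateral_mm"].to_numpy(float),
        tricuspid_medial=df["tricuspid_medial_mm"].to_numpy(float),
        mitral_lateral=df["mitral_lateral_mm"].to_numpy(float),
        strain=df["strain_pct"].to_numpy(float) if "strain_pct" in df.columns else None,
    )


def write_contours(polys: list[ContourPolygon], path: str | Path) -> None:
    rows = []
    for p in polys:
        for x, y in p.vertices:
            rows.append({"frame": p.frame, "chamber": p.chamber, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours(path: str | Path) -> list[ContourPolygon]:
    df = pd.read_csv(path)
    polys = []
    for (frame, chamber), g in df.groupby(["frame", "chamber"], sort=True):
        polys.append(ContourPolygon(
            vertices=g[["x_mm", "y_mm"]].to_numpy(float),
            frame=int(frame), chamber=str(chamber),
        ))
    return polys


def write_cpet_series(series: CPETSeries, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": series.time_s,
        "ve_l_min": series.ve,
        "vo2_ml_kg_min": series.vo2,
        "vco2_l_min": series.vco2,
        "phase": series.phase,
    }).to_csv(path, index=False)


def read_cpet_series(path: str | Path) -> CPETSeries:
    df = pd.read_csv(path)
    return CPETSeries(
        time_s=df["time_s"].to_numpy(float),
        ve=df["ve_l_min"].to_numpy(float),
        vo2=df["vo2_ml_kg_min"].to_numpy(float),
        vco2=df["vco2_l_min"].to_numpy(float),
        phase=df["phase"].to_numpy(object),
    )


def write_cohort(table: CohortTable | pd.DataFrame, path: str | Path) -> None:
    df = table.df if isinstance(table, CohortTable) else table
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))
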