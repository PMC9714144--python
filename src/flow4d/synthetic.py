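"""Analytic flow phantoms and simulated cohorts.

Phantoms
--------
* ``uniform`` — constant speed everywhere; closed-form KE / KEI_EDV.
* ``rotation`` — steady rigid rotation about z with period = cycle
  length; closed orbits, 100 % residual volume.
* ``plug_transit`` — a box chamber of length L voxels along x inside a
  slightly larger grid. During diastole a uniform plug flows in through
  the x = 0 face; during systole a faster plug exits at x = L. With
  diastolic and systolic transit distances a and b (in voxels), the
  end-diastolic blood partitions per unit length as::

      direct   = max(0, a + b - L)
      retained = a - direct
      delayed  = b - direct
      residual = L - a - b + direct

  each scaled to % of L. The plug speeds are solved so that the exact
  time integral of the linearly-interpolated frame waveform equals a and
  b; combined with integer a, b (chamber boundaries fall between voxel
  centers) the ground truth is exact, not approximate.
* ``two_channel`` — the plug channel in parallel with an equal-volume
  static channel, which guarantees all four components are non-zero
  (volume-weighted average with (0, 0, 0, 100)).

Phantom masks are static, so ED/ES frames are declared in the ground
truth rather than inferred from the (constant) volume curve; the
volume-curve inference path is exercised by a deforming mask whose
per-frame volumes are programmed.

Cohorts
-------
Per-variable marginals follow the reporting style of the study tables:
normal for mean +/- SD variables (truncated to physical ranges),
log-normal matched to median/IQR for skewed variables. Cross-variable
dependence uses a Gaussian copula; by default the only planted
correlation is remodelling index vs RV direct flow (r = -0.624), the
association highlighted by the study. Generation is bit-reproducible for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import RV, CohortTable, CPETSeries, LandmarkCurves, PhaseMask4D, VelocityField4D

__all__ = [
    "PhantomSpec", "CohortSpec", "VariableSpec",
    "make_phantom", "make_deforming_mask", "make_cohort",
    "make_cpet_series", "make_landmark_curves", "make_regression_design",
    "plug_fractions", "DEFAULT_VARIABLES",
]


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, timing and speeds of an analytic phantom.

    ``a_voxels`` / ``b_voxels`` are the diastolic inflow and systolic
    outflow transit distances in voxel lengths (integers keep the ground
    truth exact); they determine the plug speeds, not vice versa.
    """

    kind: str = "two_channel"           # uniform | rotation | plug_transit | two_channel
    length_voxels: int = 40             # chamber length L along x
    cross_section: tuple[int, int] = (10, 20)   # (y, z) voxels per channel
    margin_voxels: int = 4              # grid margin on each x side
    voxel_size_mm: float = 2.0
    n_frames: int = 30
    frame_interval_ms: float = 30.0
    systole_frames: int = 12            # frames 0..systole_frames are systolic
    a_voxels: int = 24
    b_voxels: int = 28
    uniform_speed_cms: float = 10.0     # for kind='uniform'
    venc_cms: float = 150.0

    def __post_init__(self) -> None:
        if self.kind not in {"uniform", "rotation", "plug_transit", "two_channel"}:
            raise ValueError(f"unknown phantom kind '{self.kind}'")
        if self.kind in {"plug_transit", "two_channel"}:
            if not (0 < self.a_voxels < self.length_voxels):
                raise ValueError("need 0 < a < L (whole-chamber transit rejected)")
            if not (0 < self.b_voxels < self.length_voxels):
                raise ValueError("need 0 < b < L (whole-chamber transit rejected)")
            if not (1 <= self.systole_frames < self.n_frames - 1):
                raise ValueError("systole must leave at least 2 diastolic frames")


def plug_fractions(L: int, a: int, b: int) -> dict[str, float]:
    """Closed-form component percentages of the plug-transit chamber."""
    direct = max(0, a + b - L)
    return {
        "direct_flow": 100.0 * direct / L,
        "retained_inflow": 100.0 * (a - direct) / L,
        "delayed_ejection_flow": 100.0 * (b - direct) / L,
        "residual_volume": 100.0 * (L - a - b + direct) / L,
    }


def _plug_speeds(spec: PhantomSpec) -> tuple[float, float]:
    """Solve plug speeds (cm/s) so the exact integral of the
    piecewise-linear frame waveform equals a and b voxel-lengths.

    Forward over systole (frames 0..n_sys, all systolic nodes):
    b = u_s * n_sys * dt. Backward over the preceding diastole the two
    boundary intervals blend u_s and u_d linearly, giving
    a = u_d * (T_d - dt) + u_s * dt.
    """
    dx = spec.voxel_size_mm
    dt = spec.frame_interval_ms
    n_sys = spec.systole_frames
    n_dia = spec.n_frames - n_sys
    b_mm = spec.b_voxels * dx
    a_mm = spec.a_voxels * dx
    u_s = b_mm / (n_sys * dt)                       # mm/ms
    u_d = (a_mm - u_s * dt) / ((n_dia - 1) * dt)
    if u_d <= 0:
        raise ValueError("infeasible timing: diastolic speed would be <= 0")
    return u_s * 100.0, u_d * 100.0                 # mm/ms -> cm/s


def make_phantom(spec: PhantomSpec) -> tuple[VelocityField4D, PhaseMask4D, dict]:
    """Build (field, mask, ground_truth) for an analytic phantom.

    ``ground_truth`` carries the declared ED/ES frames, the component
    fractions where defined, and closed-form KE quantities for the
    uniform phantom. All speeds respect the declared VENC.
    """
    dx = spec.voxel_size_mm
    T = spec.n_frames
    if spec.kind == "uniform":
        nx = ny = nz = 12
        vel = np.zeros((nx, ny, nz, T, 3))
        vel[..., 0] = spec.uniform_speed_cms
        labels = np.zeros((nx, ny, nz, T), dtype=np.uint8)
        labels[2:-2, 2:-2, 2:-2, :] = RV
        mask = PhaseMask4D(labels, np.full(3, dx), spec.frame_interval_ms)
        speed_ms = spec.uniform_speed_cms / 100.0
        gt = {
            "ed_frame": 0, "es_frame": T // 2,
            "kei_edv_uj_ml": 0.5 * 1060.0 * speed_ms**2,  # J/m^3 == uJ/ml
            "ke_uj_per_ml_of_pool": 0.5 * 1060.0 * speed_ms**2,
            "fractions": None,
        }
    elif spec.kind == "rotation":
        nx = ny = 21
        nz = 9
        cx = (nx - 1) / 2 * dx
        cy = (ny - 1) / 2 * dx
        omega = 2 * np.pi / (T * spec.frame_interval_ms)   # rad/ms
        x = np.arange(nx) * dx
        y = np.arange(ny) * dx
        X, Y = np.meshgrid(x, y, indexing="ij")
        vx = -omega * (Y - cy) * 100.0      # mm/ms -> cm/s
        vy = omega * (X - cx) * 100.0
        vel = np.zeros((nx, ny, nz, T, 3))
        vel[..., 0] = vx[:, :, None, None]
        vel[..., 1] = vy[:, :, None, None]
        R = ((X - cx) ** 2 + (Y - cy) ** 2) ** 0.5
        r_core = (nx - 1) / 4 * dx
        core = R <= r_core                       # seeding disk at the ED frame
        dilated = R <= r_core + 0.75 * dx        # absorbs nearest-node rounding
        lab_core = np.zeros((nx, ny, nz), dtype=np.uint8)
        lab_core[core, 2:-2] = RV
        lab_dil = np.zeros((nx, ny, nz), dtype=np.uint8)
        lab_dil[dilated, 2:-2] = RV
        # membership on non-seeding frames uses the one-voxel-dilated disk so
        # a closed rim orbit cannot round to a node just outside the label
        labels = np.repeat(lab_dil[:, :, :, None], T, axis=3)
        labels[..., 0] = lab_core
        mask = PhaseMask4D(labels, np.full(3, dx), spec.frame_interval_ms)
        gt = {"ed_frame": 0, "es_frame": T // 2, "omega_rad_per_ms": omega,
              "fractions": {"direct_flow": 0.0, "retained_inflow": 0.0,
                            "delayed_ejection_flow": 0.0, "residual_volume": 100.0}}
    else:
        L, m = spec.length_voxels, spec.margin_voxels
        wy, nz = spec.cross_section
        nx = L + 2 * m
        two = spec.kind == "two_channel"
        ny = 2 * wy if two else wy
        u_s, u_d = _plug_speeds(spec)
        if max(u_s, u_d) > spec.venc_cms:
            raise ValueError("plug speeds exceed the declared VENC")
        waveform = np.full(T, u_d)
        waveform[: spec.systole_frames + 1] = u_s   # frames 0..n_sys systolic
        vel = np.zeros((nx, ny, nz, T, 3))
        vel[:, :wy, :, :, 0] = waveform[None, None, None, :]  # flow slab
        labels = np.zeros((nx, ny, nz, T), dtype=np.uint8)
        labels[m:m + L, :, :, :] = RV
        mask = PhaseMask4D(labels, np.full(3, dx), spec.frame_interval_ms)
        frac = plug_fractions(L, spec.a_voxels, spec.b_voxels)
        if two:
            frac = {k: v / 2 for k, v in frac.items()}
            frac["residual_volume"] += 50.0
        gt = {
            "ed_frame": 0, "es_frame": spec.systole_frames,
            "fractions": frac, "u_systole_cms": u_s, "u_diastole_cms": u_d,
            "a_voxels": spec.a_voxels, "b_voxels": spec.b_voxels,
        }
    fld = VelocityField4D(
        velocity=vel, voxel_size=np.full(3, dx),
        frame_interval=spec.frame_interval_ms, venc=spec.venc_cms,
    )
    return fld, mask, gt


def make_deforming_mask(target_volumes_ml, voxel_size_mm: float = 2.0,
                        frame_interval_ms: float = 30.0,
                        ventricle: int = RV) -> PhaseMask4D:
    """A mask whose per-frame voxel count realizes programmed volumes.

    Voxels fill a box in lexicographic order until round(V / voxel volume)
    voxels are labelled, so the volume curve (hence EDV/ESV) is exact to
    within half a voxel volume of the programmed values.
    """
    vols = np.asarray(target_volumes_ml, dtype=float)
    voxvol = voxel_size_mm**3 / 1000.0
    counts = np.round(vols / voxvol).astype(int)
    if np.any(counts < 1):
        raise ValueError("every frame must keep at least one labelled voxel")
    side = int(np.ceil(counts.max() ** (1 / 3))) + 2
    labels = np.zeros((side, side, side, len(vols)), dtype=np.uint8)
    flat = labels.reshape(-1, len(vols))
    for f, c in enumerate(counts):
        flat[:c, f] = ventricle
    return PhaseMask4D(labels, np.full(3, voxel_size_mm), frame_interval_ms)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class VariableSpec:
    """Marginal distribution of one cohort variable in both groups.

    ``kind='normal'`` takes (mean, sd); ``kind='lognormal'`` takes
    (median, IQR) and solves sigma = asinh(IQR / (2 median)) / z75.
    """

    name: str
    kind: str                     # 'normal' | 'lognormal'
    control: tuple[float, float]
    pah: tuple[float, float]
    lower: float | None = None
    upper: float | None = None

    def ppf(self, u: np.ndarray, group: str) -> np.ndarray:
        p1, p2 = self.control if group == "control" else self.pah
        if self.kind == "normal":
            lo = -np.inf if self.lower is None else (self.lower - p1) / p2
            hi = np.inf if self.upper is None else (self.upper - p1) / p2
            return sps.truncnorm.ppf(u, lo, hi, loc=p1, scale=p2)
        if self.kind == "lognormal":
            z75 = sps.norm.ppf(0.75)
            mu = np.log(p1)
            sigma = np.arcsinh(p2 / (2.0 * p1)) / z75
            return np.exp(mu + sigma * sps.norm.ppf(u))
        raise ValueError(f"unknown marginal kind '{self.kind}'")


# Summary statistics of the study tables: mean +/- SD for symmetric
# variables, median (IQR) for skewed ones.
_V = VariableSpec
DEFAULT_VARIABLES = [
    _V("age", "normal", (46, 14), (46, 11), lower=18, upper=85),
    _V("bsa", "normal", (1.7, 0.2), (1.6, 0.2), lower=1.0, upper=2.6),
    _V("lvedv_i", "normal", (76, 11), (76, 34), lower=20),
    _V("lvesv_i", "normal", (32, 6), (30, 21), lower=5),
    _V("rvedv_i", "normal", (74, 13), (102, 41), lower=20),
    _V("rvesv_i", "normal", (35, 8), (61, 31), lower=5),
    _V("lvef", "normal", (59, 5), (62, 9), lower=15, upper=80),
    _V("rvef", "normal", (54, 6), (42, 12), lower=10, upper=80),
    _V("remodelling_index", "normal", (0.97, 0.10), (1.43, 0.64), lower=0.4),
    _V("tapse", "normal", (19.8, 2.8), (15.0, 3.9), lower=4),
    _V("rv_gls", "normal", (24.3, 3.9), (17.9, 4.7), lower=3),
    _V("ra_area", "normal", (19.3, 4.0), (25.3, 11.2), lower=6),
    _V("pa_rac", "normal", (56, 20), (25, 13), lower=2),
    _V("lv_direct", "lognormal", (34, 10), (31, 12)),
    _V("lv_retained", "lognormal", (17, 5), (17, 8)),
    _V("lv_delayed", "lognormal", (17, 5), (16, 7)),
    _V("lv_residual", "lognormal", (33, 6), (36, 10)),
    _V("rv_direct", "lognormal", (37, 7), (24, 16)),
    _V("rv_retained", "lognormal", (16, 6), (16, 5)),
    _V("rv_delayed", "lognormal", (17, 5), (14, 6)),
    _V("rv_residual", "lognormal", (29, 10), (44, 16)),
    _V("lv_peak_sys_keiedv", "lognormal", (16.1, 5.1), (19.3, 15.0)),
    _V("lv_avg_sys_keiedv", "lognormal", (8.9, 3.1), (11.5, 8.0)),
    _V("lv_peak_e_keiedv", "lognormal", (27.0, 12.0), (19.0, 17.4)),
    _V("rv_peak_sys_keiedv", "lognormal", (21.2, 8.5), (19.4, 18.3)),
    _V("rv_avg_sys_keiedv", "lognormal", (12.2, 4.5), (10.4, 6.9)),
    _V("rv_peak_e_keiedv", "lognormal", (13.9, 7.6), (8.4, 6.3)),
    _V("ke_discordance", "lognormal", (1.30, 0.53), (0.94, 0.66)),
    _V("ffr", "lognormal", (1.24, 0.60), (0.51, 0.40)),
    _V("peak_vo2", "lognormal", (22.6, 10.5), (13.2, 4.4)),
    _V("pct_pred_vo2", "lognormal", (87, 33), (48, 23)),
    _V("vevco2_slope", "lognormal", (27, 4), (41, 10)),
]


@dataclass
class CohortSpec:
    """Cohort sizes, marginals and copula correlations for a simulated study."""

    n_control: int = 51
    n_pah: int = 45
    variables: list[VariableSpec] = field(
        default_factory=lambda: [replace(v) for v in DEFAULT_VARIABLES])
    #: pairwise Gaussian-copula correlations, e.g. {("remodelling_index",
    #: "rv_direct"): -0.624}; unlisted pairs are independent.
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("remodelling_index", "rv_direct"): -0.624}
    )

    def correlation_matrix(self) -> np.ndarray:
        names = [v.name for v in self.variables]
        k = len(names)
        R = np.eye(k)
        for (a, b), r in self.correlations.items():
            i, j = names.index(a), names.index(b)
            R[i, j] = R[j, i] = r
        eig = np.linalg.eigvalsh(R)
        if eig.min() <= 0:
            raise ValueError("infeasible correlation matrix (not positive definite)")
        return R


def make_cohort(spec: CohortSpec | None = None, seed: int = 0) -> CohortTable:
    """Sample a control/PAH cohort table via a Gaussian copula.

    Marginals and group effects follow the declared :class:`VariableSpec`
    list; the result is bit-reproducible for a fixed seed.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    R = spec.correlation_matrix()
    chol = np.linalg.cholesky(R)
    names = [v.name for v in spec.variables]
    rows = []
    for group, n in (("control", spec.n_control), ("PAH", spec.n_pah)):
        z = rng.standard_normal((n, len(names))) @ chol.T
        u = sps.norm.cdf(z)
        data = {v.name: v.ppf(u[:, i], group) for i, v in enumerate(spec.variables)}
        df = pd.DataFrame(data)
        df.insert(0, "group", group)
        df["sex"] = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
        if group == "PAH":
            df["risk_grade"] = rng.choice([1, 2, 3], size=n, p=[0.4, 0.4, 0.2])
        else:
            df["risk_grade"] = np.nan
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", [f"S{i:03d}" for i in range(len(out))])
    return CohortTable(out)


def make_regression_design(seed: int = 0, n: int = 96,
                           betas: tuple[float, float] = (0.6, 0.2),
                           n_decoys: int = 5, signal_corr: float = 0.5,
                           noise_sd: float = 0.4) -> pd.DataFrame:
    """Planted-support design for exercising stepwise selection.

    Two true predictors (coefficients ``betas``) plus independent decoys;
    the outcome is their linear combination plus Gaussian noise. The two
    signals are correlated (default r = 0.5, the collinearity typical of
    physiological covariates), which also keeps the weaker signal
    detectable by a univariate screen: with independent signals the
    strong signal's variance acts as extra noise in the weak signal's
    univariate test and caps its screen power near 0.9 even noiselessly.
    Columns: x1, x2, d0..d{k-1}, y.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x1 = z[:, 0]
    x2 = signal_corr * z[:, 0] + np.sqrt(1 - signal_corr**2) * z[:, 1]
    decoys = rng.standard_normal((n, n_decoys))
    y = betas[0] * x1 + betas[1] * x2 + rng.normal(0.0, noise_sd, n)
    df = pd.DataFrame(np.c_[x1, x2, decoys],
                      columns=["x1", "x2"] + [f"d{i}" for i in range(n_decoys)])
    df["y"] = y
    return df


# ---------------------------------------------------------------------------
# CPET and landmark series
# ---------------------------------------------------------------------------

def make_cpet_series(slope: float = 30.0, peak: float = 20.0,
                     noise_sd: float = 0.0, seed: int = 0,
                     intercept: float = 3.0,
                     rest_s: float = 120.0, exercise_s: float = 600.0,
                     recovery_s: float = 120.0) -> CPETSeries:
    """Synthetic 10-s averaged CPET series with planted peak VO2 and
    VE/VCO2 slope.

    VO2 ramps linearly to ``peak`` at the last exercise sample; VE is
    ``slope * VCO2 + intercept`` plus optional white noise, so with
    ``noise_sd=0`` the slope is recovered exactly by OLS.
    """
    if peak <= 0 or slope <= 0:
        raise ValueError("peak and slope must be positive")
    dt = 10.0
    t = np.arange(0.0, rest_s + exercise_s + recovery_s, dt)
    phase = np.where(t < rest_s, "rest",
                     np.where(t < rest_s + exercise_s, "exercise", "recovery"))
    rng = np.random.default_rng(seed)
    vo2 = np.full_like(t, 0.15 * peak)
    ex = phase == "exercise"
    ramp = (t[ex] - t[ex][0]) / (t[ex][-1] - t[ex][0])
    vo2[ex] = 0.15 * peak + (peak - 0.15 * peak) * ramp
    vo2[phase == "recovery"] = 0.5 * peak
    vco2 = 0.3 + 2.2 * vo2 / peak   # L/min, rises with effort
    ve = slope * vco2 + intercept + rng.normal(0.0, noise_sd, size=len(t))
    ve = np.maximum(ve, 0.0)
    return CPETSeries(time_s=t, ve=ve, vo2=vo2, vco2=vco2, phase=phase)


def make_landmark_curves(tapse_mm: float = 18.0, mitral_peak_mm: float = 14.0,
                         offset_frames: int = 0, n_frames: int = 30,
                         frame_interval_ms: float = 30.0,
                         es_frame: int | None = None,
                         gls_pct: float | None = None,
                         seed: int = 0) -> LandmarkCurves:
    """Half-sine displacement curves with programmed peaks and peak-time
    offsets; the optional strain curve is scaled so its ES value is
    ``gls_pct`` exactly.
    """
    if es_frame is None:
        es_frame = n_frames // 2 - 1
    t = np.arange(n_frames) * frame_interval_ms

    def bump(peak_amp, peak_frame):
        curve = np.zeros(n_frames)
        rise = np.sin(np.linspace(0, np.pi / 2, peak_frame + 1))
        fall = np.cos(np.linspace(0, np.pi / 2, n_frames - peak_frame))
        curve[: peak_frame + 1] = rise
        curve[peak_frame:] = fall
        return peak_amp * curve

    tv_peak = es_frame
    mv_peak = es_frame + offset_frames
    if not (0 < mv_peak < n_frames):
        raise ValueError("mitral peak frame out of range")
    tv_lat = bump(tapse_mm, tv_peak)
    tv_med = bump(0.8 * tapse_mm, tv_peak)
    mv_lat = bump(mitral_peak_mm, mv_peak)
    strain = None
    if gls_pct is not None:
        strain = bump(1.0, es_frame)
        strain *= gls_pct / strain[es_frame]
    return LandmarkCurves(
        time_ms=t, tricuspid_lateral=tv_lat, tricuspid_medial=tv_med,
        mitral_lateral=mv_lat, strain=strain,
    )
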