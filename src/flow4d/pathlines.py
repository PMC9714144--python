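"""Spatiotemporal velocity interpolation and particle advection.

The velocity field is interpolated trilinearly in space and linearly in
time between the two bracketing cardiac phases, with periodic wrap of the
cycle (retrospectively gated CMR is cyclic). Particles are advected with
classic fixed-step 4th-order Runge-Kutta, forward or backward in time,
with positions recorded at every frame time crossed. A particle whose
sub-step leaves the grid bounding box keeps its last position and is
flagged ``left_grid``; downstream classification treats that identically
to having left the chamber.

The interpolation domain (bounding box) is the voxel-center hull
``[0, (N-1)*voxel_size]`` along each axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .data_model import PhaseMask4D, VelocityField4D

__all__ = ["Pathline", "VelocityInterpolator", "interpolate_velocity",
           "advect", "advect_batch", "seed_particles"]

# cm/s -> mm/ms
_CMS_TO_MM_MS = 0.01


@dataclass
class Pathline:
    """One particle's time-ordered trajectory at frame resolution.

    ``inside`` flags are filled in by the flow-component stage against the
    frame-matched mask of the seeding ventricle; ``status`` is 'complete'
    or 'left_grid'.
    """

    times: np.ndarray       # ms, ordered as traced (monotone in |t - t0|)
    positions: np.ndarray   # (n_samples, 3) mm
    status: str = "complete"
    inside: np.ndarray | None = None

    @property
    def seed(self) -> np.ndarray:
        return self.positions[0]


class VelocityInterpolator:
    """Trilinear-in-space, linear-in-time, time-periodic field interpolator."""

    def __init__(self, fld: VelocityField4D):
        self.field = fld
        nx, ny, nz = fld.grid_shape
        dx, dy, dz = fld.voxel_size
        self.cycle = fld.cycle_duration
        # time axis extended by one wrapped frame so queries in
        # [T-1, T]*dt interpolate toward frame 0
        t_ext = np.arange(fld.n_frames + 1) * fld.frame_interval
        values = np.concatenate([fld.velocity, fld.velocity[:, :, :, :1]], axis=3)
        self._lo = np.zeros(3)
        self._hi = np.array([(nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz])
        self._rgi = RegularGridInterpolator(
            (np.arange(nx) * dx, np.arange(ny) * dy, np.arange(nz) * dz, t_ext),
            values, method="linear", bounds_error=True,
        )

    def in_bounds(self, pos: np.ndarray) -> np.ndarray:
        """Vectorized bounding-box test for (n, 3) positions in mm."""
        pos = np.atleast_2d(pos)
        return np.all((pos >= self._lo) & (pos <= self._hi), axis=1)

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Velocity in cm/s at (n, 3) positions (mm) and a scalar time (ms)."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        tq = np.full((len(pos), 1), float(t) % self.cycle)
        return self._rgi(np.hstack([pos, tq]))

    def eval_clamped(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Evaluate with positions clamped to the box (used inside RK4 sub-steps)."""
        pos = np.clip(np.atleast_2d(pos), self._lo, self._hi)
        return self(pos, t)


def interpolate_velocity(fld: VelocityField4D, position, time: float) -> np.ndarray:
    """Velocity vector (cm/s) at one position (mm) and time (ms).

    Exact at voxel centers on frame times; raises if the position lies
    outside the grid bounding box.
    """
    interp = VelocityInterpolator(fld)
    position = np.asarray(position, dtype=float)
    if not interp.in_bounds(position)[0]:
        raise ValueError(f"position {position} outside grid bounding box")
    return interp(position, time)[0]


def _resolve_dt(fld: VelocityField4D, dt: float | None) -> float:
    if dt is None:
        return fld.frame_interval / 5.0
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > fld.frame_interval:
        warnings.warn(
            f"dt={dt} ms exceeds the frame interval "
            f"({fld.frame_interval} ms); clamping", stacklevel=2,
        )
        dt = fld.frame_interval
    return dt


def _sample_times(fld: VelocityField4D, t0: float, t1: float) -> np.ndarray:
    """Frame times crossed between t0 and t1 (inclusive endpoints), traced order."""
    dt_f = fld.frame_interval
    if t1 >= t0:
        first = np.ceil(t0 / dt_f)
        last = np.floor(t1 / dt_f)
        knots = np.arange(first, last + 1) * dt_f
    else:
        first = np.floor(t0 / dt_f)
        last = np.ceil(t1 / dt_f)
        knots = np.arange(first, last - 1, -1) * dt_f
    ts = np.concatenate([[t0], knots, [t1]])
    # drop duplicates at endpoints
    keep = np.ones(len(ts), dtype=bool)
    keep[1:] = np.abs(np.diff(ts)) > 1e-9
    return ts[keep]


def advect_batch(
    fld: VelocityField4D,
    seeds: np.ndarray,
    t0: float,
    t1: float,
    dt: float | None = None,
    interp: VelocityInterpolator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advect many particles together through the periodic field.

    Parameters
    ----------
    seeds : (n, 3) positions in mm at time ``t0``.
    t0, t1 : ms; ``t1 < t0`` integrates backward.
    dt : RK4 step in ms (default frame_interval/5, clamped to one frame).

    Returns
    -------
    times : (m,) sample times (frame times crossed, plus endpoints).
    positions : (m, n, 3) particle positions; frozen after grid exit.
    left_grid : (n,) bool flags.
    """
    if interp is None:
        interp = VelocityInterpolator(fld)
    dt = _resolve_dt(fld, dt)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if not np.all(interp.in_bounds(seeds)):
        raise ValueError("all seeds must start inside the grid bounding box")

    times = _sample_times(fld, t0, t1)
    n = len(seeds)
    out = np.empty((len(times), n, 3))
    out[0] = seeds
    left = np.zeros(n, dtype=bool)

    pos = seeds.copy()
    for m in range(1, len(times)):
        ta, tb = times[m - 1], times[m]
        span = tb - ta
        nsub = max(1, int(np.ceil(abs(span) / dt - 1e-12)))
        h = span / nsub
        for s in range(nsub):
            t = ta + s * h
            active = ~left
            if not np.any(active):
                break
            p = pos[active]
            k1 = interp.eval_clamped(p, t) * _CMS_TO_MM_MS
            k2 = interp.eval_clamped(p + 0.5 * h * k1, t + 0.5 * h) * _CMS_TO_MM_MS
            k3 = interp.eval_clamped(p + 0.5 * h * k2, t + 0.5 * h) * _CMS_TO_MM_MS
            k4 = interp.eval_clamped(p + h * k3, t + h) * _CMS_TO_MM_MS
            new_p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            # a sub-step position outside the box terminates the particle
            ok = (
                interp.in_bounds(new_p)
                & interp.in_bounds(p + 0.5 * h * k1)
                & interp.in_bounds(p + 0.5 * h * k2)
                & interp.in_bounds(p + h * k3)
            )
            idx = np.flatnonzero(active)
            pos[idx[ok]] = new_p[ok]
            left[idx[~ok]] = True
        out[m] = pos
    return times, out, left


def advect(
    fld: VelocityField4D,
    seed,
    t0: float,
    t1: float,
    dt: float | None = None,
) -> Pathline:
    """Trace a single particle; see :func:`advect_batch` for semantics."""
    times, positions, left = advect_batch(fld, np.asarray(seed, float)[None, :], t0, t1, dt)
    return Pathline(
        times=times,
        positions=positions[:, 0, :],
        status="left_grid" if left[0] else "complete",
    )


def seed_particles(mask: PhaseMask4D, frame: int, ventricle: int,
                   spacing: int = 1) -> np.ndarray:
    """Seeds at voxel centers of one ventricle label at a given frame.

    ``spacing`` keeps every spacing-th voxel along each axis (1 = every
    labelled voxel). Order is deterministic (lexicographic i, j, k); seed
    count x voxel volume x spacing^3 approximates the chamber volume.
    """
    if spacing < 1 or int(spacing) != spacing:
        raise ValueError("spacing must be an integer >= 1")
    sel = mask.labels[..., frame] == ventricle
    idx = np.argwhere(sel)
    if len(idx) == 0:
        raise ValueError(f"ventricle {ventricle} empty at frame {frame}")
    if spacing > 1:
        keep = np.all(idx % spacing == 0, axis=1)
        idx = idx[keep]
    return idx * mask.voxel_size
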