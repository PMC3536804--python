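"""Overdamped Langevin trajectory generation with camera-noise modelling.

The integrator is Euler--Maruyama on dr = -D grad(V) dt + sqrt(2 D) dW
(k_BT = 1) with a configurable number of substeps per camera frame, so
the integration step is much shorter than the relaxation times of the
confining potential.  The same code path serves as fixture generator for
the test suite and as ground truth for the recovery benchmarks.
"""

from __future__ import annotations

import math

import numpy as np

from .potentials import FieldSchedule, Potential, RegionDiffusivity
from .trajectory import Trajectory

__all__ = ["simulate", "add_camera_noise", "SimulationError"]


class SimulationError(RuntimeError):
    pass


_STABILITY_MSG = ("drift step exceeded {lim:.3g} um at position {pos}; "
                  "the integrator step is too coarse for this landscape -- "
                  "raise `substeps`")


def _simulate_static(potential: Potential, diffusivity, n_frames, frame_dt,
                     substeps, rng, r0, keep_substeps, stability_limit):
    ndim = potential.ndim
    h = frame_dt / substeps
    n_sub = n_frames * substeps
    noise = rng.standard_normal((n_sub, ndim))
    const_d = not isinstance(diffusivity, RegionDiffusivity)
    if const_d:
        d_val = float(diffusivity)
        if d_val <= 0:
            raise ValueError("diffusivity must be positive")
        amp = math.sqrt(2.0 * d_val * h)
    fine = np.empty((n_sub + 1, ndim)) if keep_substeps else None
    frames = np.empty((n_frames, ndim))
    lim = stability_limit

    if ndim == 1:
        x = float(r0[0])
        grad = potential.grad1
        for i in range(n_sub):
            if i % substeps == 0:
                frames[i // substeps, 0] = x
            if fine is not None:
                fine[i, 0] = x
            if const_d:
                dloc, a = d_val, amp
            else:
                dloc = diffusivity.at1(x)
                a = math.sqrt(2.0 * dloc * h)
            drift = -dloc * grad(x) * h
            if abs(drift) > lim:
                raise SimulationError(_STABILITY_MSG.format(lim=lim, pos=(x,)))
            x += drift + a * noise[i, 0]
        if fine is not None:
            fine[n_sub, 0] = x
    else:
        x, y = float(r0[0]), float(r0[1])
        grad = potential.grad2
        for i in range(n_sub):
            if i % substeps == 0:
                j = i // substeps
                frames[j, 0] = x
                frames[j, 1] = y
            if fine is not None:
                fine[i, 0] = x
                fine[i, 1] = y
            if const_d:
                dloc, a = d_val, amp
            else:
                dloc = diffusivity.at2(x, y)
                a = math.sqrt(2.0 * dloc * h)
            gx, gy = grad(x, y)
            dx = -dloc * gx * h
            dy = -dloc * gy * h
            if abs(dx) > lim or abs(dy) > lim:
                raise SimulationError(_STABILITY_MSG.format(lim=lim, pos=(x, y)))
            x += dx + a * noise[i, 0]
            y += dy + a * noise[i, 1]
        if fine is not None:
            fine[n_sub] = (x, y)

    sub = None
    if keep_substeps:
        sub = fine[:n_sub].reshape(n_frames, substeps, ndim)
    return frames, sub


def _simulate_schedule(schedule: FieldSchedule, n_frames, frame_dt, substeps,
                       rng, r0, keep_substeps, stability_limit):
    ndim = schedule.ndim
    h = frame_dt / substeps
    n_sub = n_frames * substeps
    t_sub = np.arange(n_sub) * h
    k_arr = schedule.k_at(t_sub)
    amp_arr = np.sqrt(2.0 * schedule.d_at(t_sub) * h)
    dk_arr = schedule.d_at(t_sub) * k_arr * h  # drift prefactor D k dt
    noise = rng.standard_normal((n_sub, ndim))
    cx, cy = schedule.center
    frames = np.empty((n_frames, ndim))
    fine = np.empty((n_sub, ndim)) if keep_substeps else None
    lim = stability_limit
    x = float(r0[0])
    y = float(r0[1]) if ndim == 2 else 0.0
    for i in range(n_sub):
        if i % substeps == 0:
            j = i // substeps
            frames[j, 0] = x
            if ndim == 2:
                frames[j, 1] = y
        if fine is not None:
            fine[i, 0] = x
            if ndim == 2:
                fine[i, 1] = y
        dk = dk_arr[i]
        dx = -dk * (x - cx)
        if abs(dx) > lim:
            raise SimulationError(_STABILITY_MSG.format(lim=lim, pos=(x, y)))
        x += dx + amp_arr[i] * noise[i, 0]
        if ndim == 2:
            y += -dk * (y - cy) + amp_arr[i] * noise[i, 1]
    sub = fine.reshape(n_frames, substeps, ndim) if keep_substeps else None
    return frames, sub


def simulate(potential, diffusivity=None, n_frames: int = 2000,
             frame_dt: float = 0.025, substeps: int = 20,
             seed=None, r0=None, keep_substeps: bool = False,
             stability_limit: float = 0.2, label: str = "") -> Trajectory:
    """Generate one trajectory by Euler--Maruyama integration.

    Parameters
    ----------
    potential : Potential or FieldSchedule
        Static landscape, or a slowly varying harmonic schedule (in which
        case ``diffusivity`` is taken from the schedule).
    diffusivity : float or RegionDiffusivity
        Diffusion coefficient in um^2/s; a :class:`RegionDiffusivity`
        gives piecewise-constant spatial variation (Ito convention).
    n_frames : int
        Number of recorded camera frames (positions at frame starts).
    frame_dt : float
        Frame interval in seconds.
    substeps : int
        Integration steps per frame, >= 10 so the step is well below the
        confinement relaxation time.
    keep_substeps : bool
        Retain the fine positions, required later for exposure-time blur.
    stability_limit : float
        Maximum tolerated deterministic displacement per integration step
        (um); larger drifts abort with guidance to raise ``substeps``.

    The run is deterministic for a fixed ``seed``.
    """
    if substeps < 10:
        raise ValueError("substeps must be >= 10")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    if r0 is None:
        r0 = (0.0, 0.0)
    if np.isscalar(r0):
        r0 = (float(r0),)
    if isinstance(potential, FieldSchedule):
        frames, sub = _simulate_schedule(potential, n_frames, frame_dt,
                                         substeps, rng, r0, keep_substeps,
                                         stability_limit)
    else:
        if diffusivity is None:
            raise ValueError("diffusivity is required for a static potential")
        frames, sub = _simulate_static(potential, diffusivity, n_frames,
                                       frame_dt, substeps, rng, r0,
                                       keep_substeps, stability_limit)
    times = np.arange(n_frames) * frame_dt
    return Trajectory(times=times, positions=frames, frame_interval=frame_dt,
                      label=label, substep_positions=sub)


def add_camera_noise(traj: Trajectory, sigma_static: float,
                     exposure_fraction: float = 0.0, seed=None) -> Trajectory:
    """Apply camera effects to a simulated trajectory.

    Dynamic blur first: each recorded position becomes the average of the
    integrator substep positions over the first ``exposure_fraction`` of
    the frame interval (the camera integrates while the particle moves).
    Static localisation error second: i.i.d. Gaussian noise of standard
    deviation ``sigma_static`` (um) per coordinate.  Static noise sigma at
    frame interval dt inflates the apparent diffusivity by sigma^2/dt.
    """
    if sigma_static < 0:
        raise ValueError("sigma_static must be non-negative")
    if not 0.0 <= exposure_fraction <= 1.0:
        raise ValueError("exposure_fraction must be in [0, 1]")
    pos = traj.positions
    if exposure_fraction > 0.0:
        if traj.substep_positions is None:
            raise ValueError("exposure blur requires a trajectory simulated "
                             "with keep_substeps=True")
        sub = traj.substep_positions
        m = max(1, int(round(exposure_fraction * sub.shape[1])))
        pos = sub[:, :m, :].mean(axis=1)
    if sigma_static > 0.0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, sigma_static, size=pos.shape)
    elif exposure_fraction == 0.0:
        pos = pos.copy()
    return traj.with_positions(pos)
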