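"""Trajectory containers, I/O and summary statistics.

Positions are in micrometres, times in seconds and energies in units of
k_BT throughout the package.  The canonical on-disk format is a delimited
text table with header ``frame,t_s,x_um,y_um`` (1D records omit ``y_um``),
which matches common single-particle-tracking exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "summarize",
    "load_config",
    "clip_to_disc",
]


class TrajectoryError(ValueError):
    """Raised when a trajectory record violates its invariants."""


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered sequence of localisations for one particle.

    Parameters
    ----------
    times : array of float
        Observation times in seconds, strictly increasing, at least two.
    positions : array of float, shape ``(n, d)`` with d in {1, 2}
        Localised positions in micrometres.
    frame_interval : float
        Nominal frame interval in seconds.  Per-step intervals are always
        derived from ``times``; this is metadata.
    label : str
        Free-text identifier.
    substep_positions : ndarray or None
        Optional fine-grained integrator positions, shape
        ``(n_frames, substeps, d)``; kept by the simulator when motion-blur
        modelling is requested downstream.
    """

    times: np.ndarray
    positions: np.ndarray
    frame_interval: float
    label: str = ""
    substep_positions: np.ndarray | None = field(default=None, repr=False, compare=False)
    # False marks steps that span a clipped-out portion of the record;
    # such pseudo-steps are excluded from all per-step statistics.
    step_valid: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
        if times.ndim != 1 or times.size < 2:
            raise TrajectoryError("a trajectory needs at least 2 time points")
        if pos.shape[0] != times.size:
            raise TrajectoryError("times and positions length mismatch")
        if pos.shape[1] not in (1, 2):
            raise TrajectoryError("only 1D and 2D trajectories are supported")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(pos)):
            raise TrajectoryError("non-finite entries in trajectory")
        if np.any(np.diff(times) <= 0):
            raise TrajectoryError("non-increasing time")
        if not self.frame_interval > 0:
            raise TrajectoryError("frame_interval must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.n_points - 1

    @property
    def dt(self) -> np.ndarray:
        """Per-step time intervals in seconds (all positive)."""
        return np.diff(self.times)

    @property
    def steps(self) -> np.ndarray:
        """Per-step displacement vectors, shape ``(n_steps, d)``."""
        return np.diff(self.positions, axis=0)

    @property
    def valid_steps(self) -> np.ndarray:
        """Boolean mask of genuine (non-gap) steps."""
        if self.step_valid is None:
            return np.ones(self.n_steps, bool)
        return np.asarray(self.step_valid, bool)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def gap_flags(self, factor: float = 5.0) -> np.ndarray:
        """Boolean mask of steps whose interval exceeds ``factor`` x median dt.

        Gaps are flagged but never split: the transition likelihood is
        per-step, so irregular sampling is handled naturally.
        """
        dt = self.dt
        return dt > factor * np.median(dt)

    def with_positions(self, positions: np.ndarray) -> "Trajectory":
        return replace(self, positions=np.asarray(positions, float),
                       substep_positions=None)


def clip_to_disc(traj: Trajectory, center, radius: float) -> Trajectory:
    """Restrict a record to the neighbourhood of a confinement domain.

    Keeps the points within ``radius`` of ``center`` and marks the steps
    that span removed excursions as invalid, so the per-step likelihood
    and the mesh rule see only genuine transitions near the domain.  Long
    free-motion excursions far from a well carry no information about its
    boundary but would dominate the polynomial fit's domain.
    """
    center = np.atleast_1d(np.asarray(center, float))
    keep = np.linalg.norm(traj.positions - center, axis=1) <= radius
    if keep.sum() < 2:
        raise TrajectoryError("fewer than 2 points inside the clip region")
    idx = np.flatnonzero(keep)
    step_ok = np.diff(idx) == 1
    return replace(traj, times=traj.times[idx], positions=traj.positions[idx],
                   substep_positions=None, step_valid=step_ok)


@dataclass(frozen=True)
class RunConfig:
    """Inference configuration.

    Attributes
    ----------
    mesh_factor : float
        Mesh cell size in units of the mean step length (default 2: cells
        are twice the average displacement, so steps stay within a cell or
        reach a neighbouring one).
    polynomial_order : int
        Order C of the potential polynomial, 2..6.  Default 4; the
        inference escalates to 6 automatically when the two detected
        minima lie more than ``order_escalation_distance`` apart.
    sigma : float
        Static localisation noise in micrometres (default 0.030).  Fixed
        input of the likelihood, never inferred.
    min_points_per_cell : int
        Occupancy Ñ regarded as sufficient for meaningful per-cell
        estimates; used by the timescale checks (default 15).
    min_transitions_estimate : int
        Cells with fewer starting transitions than this inherit the
        diffusivity of the nearest estimated cell instead of receiving a
        free parameter (default 4).
    window_length, window_shift : float
        Sliding-window duration and shift in seconds (defaults 40 and 5).
    n_restarts : int
        Random optimiser restarts beyond the deterministic start.
    seed : int
        Seed for restart perturbations and any stochastic plumbing.
    """

    mesh_factor: float = 2.0
    polynomial_order: int = 4
    sigma: float = 0.030
    min_points_per_cell: int = 15
    min_transitions_estimate: int = 4
    window_length: float = 40.0
    window_shift: float = 5.0
    order_escalation_distance: float = 0.300
    gradient_at: str = "step_start"   # "step_start" | "cell_center"
    n_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.polynomial_order <= 6):
            raise ValueError("polynomial_order must be in 2..6")
        for name in ("mesh_factor", "sigma", "window_length", "window_shift"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mesh_factor <= 0 or self.window_length <= 0 or self.window_shift <= 0:
            raise ValueError("mesh_factor, window_length, window_shift must be positive")
        if self.gradient_at not in ("step_start", "cell_center"):
            raise ValueError("gradient_at must be 'step_start' or 'cell_center'")


_COLUMN_ALIASES = {
    "frame": ("frame", "frame_idx", "n"),
    "t": ("t_s", "t", "time", "time_s"),
    "x": ("x_um", "x"),
    "y": ("y_um", "y"),
}


def _resolve(columns: Sequence[str], key: str,
             dialect: Mapping[str, str] | None) -> str | None:
    if dialect and key in dialect:
        if dialect[key] not in columns:
            raise TrajectoryError(f"mapped column {dialect[key]!r} not in file")
        return dialect[key]
    for alias in _COLUMN_ALIASES[key]:
        if alias in columns:
            return alias
    return None


def read_trajectory(path: str | Path,
                    dialect: Mapping[str, str] | None = None,
                    frame_interval: float | None = None,
                    sep: str = ",",
                    label: str | None = None) -> Trajectory:
    """Read a delimited-text trajectory table.

    Columns are resolved to (frame or time, x[, y]) using standard aliases
    or an explicit ``dialect`` mapping with keys ``t``/``frame``/``x``/``y``.
    If only a frame column is present, times are ``frame * frame_interval``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = list(df.columns)
    tcol = _resolve(cols, "t", dialect)
    fcol = _resolve(cols, "frame", dialect)
    xcol = _resolve(cols, "x", dialect)
    ycol = _resolve(cols, "y", dialect)
    if xcol is None:
        raise TrajectoryError(f"missing x column among {cols}")
    if tcol is None and fcol is None:
        raise TrajectoryError(f"missing time or frame column among {cols}")
    try:
        if tcol is not None:
            times = df[tcol].to_numpy(dtype=float)
        else:
            if frame_interval is None:
                raise TrajectoryError(
                    "frame-indexed table requires an explicit frame_interval")
            times = df[fcol].to_numpy(dtype=float) * frame_interval
        x = df[xcol].to_numpy(dtype=float)
        y = df[ycol].to_numpy(dtype=float) if ycol is not None else None
    except (TypeError, ValueError) as exc:
        raise TrajectoryError(f"non-numeric entries in {path.name}: {exc}") from None
    pos = x[:, None] if y is None else np.column_stack([x, y])
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(times)))
    return Trajectory(times=times, positions=pos, frame_interval=frame_interval,
                      label=label if label is not None else path.stem)


def write_trajectory(traj: Trajectory, path: str | Path, sep: str = ",") -> Path:
    """Write the canonical ``frame,t_s,x_um[,y_um]`` table (full precision)."""
    path = Path(path)
    data = {"frame": np.arange(traj.n_points),
            "t_s": traj.times,
            "x_um": traj.positions[:, 0]}
    if traj.ndim == 2:
        data["y_um"] = traj.positions[:, 1]
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def summarize(traj: Trajectory, sigma: float = 0.030) -> dict:
    """Summary statistics of a trajectory.

    Returns duration, mean step length, the MSD-based apparent diffusivity
    ``D_app = <|dr|^2> / (2 d dt)`` and the noise-equivalent diffusivity
    ``sigma^2 / dt`` for the given static localisation noise: localisation
    error of amplitude sigma inflates the apparent diffusivity by that
    amount (e.g. sigma = 30 nm at 50 ms frames gives 0.018 um^2/s).
    """
    ok = traj.valid_steps
    steps = traj.steps[ok]
    dt = traj.dt[ok]
    d = traj.ndim
    sq = np.sum(steps ** 2, axis=1)
    d_app = float(np.sum(sq) / (2.0 * d * np.sum(dt)))
    mean_dt = float(np.mean(dt))
    return {
        "n_points": traj.n_points,
        "ndim": d,
        "duration_s": traj.duration,
        "mean_dt_s": mean_dt,
        "mean_step_um": float(np.mean(np.sqrt(sq))),
        "apparent_diffusivity_um2_s": d_app,
        "noise_diffusivity_um2_s": float(sigma ** 2 / mean_dt),
        "n_gap_steps": int(np.count_nonzero(traj.gap_flags())),
    }


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML file; keyword overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
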