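"""Time-resolved inference on sliding windows.

Slowly varying confinement (e.g. enzymatic raft destabilisation over
minutes) is tracked by re-running the MAP inference on a sliding window
of duration ``window_length`` shifted by ``window_shift``, after removing
slow drift of the confinement centre.  Validity requires a separation of
timescales

    tau_m  <<  tau_inf  <<  tau_VD

where tau_m = L^2/D is the confinement mixing time, tau_inf the window
length (which must also accumulate enough occupancy per mesh cell) and
tau_VD the characteristic time over which the fields themselves change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .inference import (InferenceResult, average_diffusivity, build_mesh,
                        fit_harmonic, infer_map, occupancy_counts)
from .trajectory import RunConfig, Trajectory

__all__ = ["TimescaleReport", "WindowedResult", "drift_correct",
           "check_timescales", "sliding_window_inference"]


@dataclass(frozen=True)
class TimescaleReport:
    tau_m: float                 # confinement mixing time L^2/D, s
    tau_inf: float               # window length, s
    tau_inf_required: float      # window length needed for <N_ij> >= N~
    tau_vd: float                # empirical field-variation time, s
    mixing_ok: bool              # tau_inf >= margin_m * tau_m
    variation_ok: bool           # tau_vd >= margin_v * tau_inf
    occupancy_ok: bool
    doubling_max_rel_change: float | None


@dataclass(frozen=True)
class WindowedResult:
    times: np.ndarray            # window midpoints, s
    results: tuple               # InferenceResult per window
    k: np.ndarray                # harmonic spring constant per window
    diffusivity: np.ndarray      # occupancy-weighted mean D per window
    occupancy: np.ndarray        # mean transitions per occupied cell
    flags: tuple                 # tuple of per-window flag tuples


def drift_correct(traj: Trajectory, window_length: float
                  ) -> tuple[Trajectory, np.ndarray]:
    """Remove slow centre-of-mass drift.

    The drift is the locally linear (Savitzky--Golay, order 1) smoothing
    of the positions over ``window_length``; it is subtracted and the
    overall mean restored, so a purely drifting record becomes constant
    and a drift-free record is (statistically) unchanged.  Returns the
    corrected trajectory and the removed drift series.
    """
    dt = float(np.median(traj.dt))
    if window_length > traj.duration:
        raise ValueError("drift window longer than the record")
    w = int(round(window_length / dt))
    w = max(3, min(w | 1, traj.n_points if traj.n_points % 2 else traj.n_points - 1))
    smooth = savgol_filter(traj.positions, w, polyorder=1, axis=0,
                           mode="interp")
    drift = smooth - traj.positions.mean(axis=0)
    corrected = traj.with_positions(traj.positions - drift)
    return corrected, drift


def _window_slices(times: np.ndarray, length: float, shift: float):
    t0 = times[0]
    out = []
    start = t0
    while start + length <= times[-1] + 1e-9:
        i0 = int(np.searchsorted(times, start - 1e-9))
        i1 = int(np.searchsorted(times, start + length + 1e-9))
        if i1 - i0 >= 3:
            out.append((i0, i1, start + length / 2.0))
        start += shift
    return out


def _infer_window(traj: Trajectory, i0: int, i1: int, config: RunConfig):
    sub = Trajectory(times=traj.times[i0:i1], positions=traj.positions[i0:i1],
                     frame_interval=traj.frame_interval, label=traj.label)
    sub, _ = drift_correct(sub, config.window_length)
    return infer_map(sub, config), sub


def sliding_window_inference(traj: Trajectory, config: RunConfig | None = None
                             ) -> WindowedResult:
    """Windowed (k, D) series: drift-correct, infer, harmonic fit, mean D.

    The mesh is rebuilt inside every window because the mesh rule depends
    on the window's mean step, which changes as the diffusivity evolves.
    Windows whose mean occupancy falls below ``min_points_per_cell`` or
    whose harmonic fit is not confining are flagged, never dropped.
    """
    config = config or RunConfig()
    slices = _window_slices(traj.times, config.window_length,
                            config.window_shift)
    if not slices:
        raise ValueError("record shorter than one window")
    times, results, ks, ds, occ, flags = [], [], [], [], [], []
    for i0, i1, tmid in slices:
        res, sub = _infer_window(traj, i0, i1, config)
        fit = fit_harmonic(res)
        wf = []
        if res.diagnostics["mean_occupancy"] < config.min_points_per_cell:
            wf.append("low_occupancy")
        if not fit.confined:
            wf.append("not_confined")
        if not res.diagnostics["converged"]:
            wf.append("not_converged")
        times.append(tmid)
        results.append(res)
        ks.append(fit.k)
        ds.append(average_diffusivity(res))
        occ.append(res.diagnostics["mean_occupancy"])
        flags.append(tuple(wf))
    return WindowedResult(times=np.asarray(times), results=tuple(results),
                          k=np.asarray(ks), diffusivity=np.asarray(ds),
                          occupancy=np.asarray(occ), flags=tuple(flags))


def _empirical_tau_vd(times: np.ndarray, series: list[np.ndarray]) -> float:
    """Time for a 10% relative change of the fastest-evolving series,
    from a linear fit to log-values (infinite when the fit is not
    distinguishable from flat at the 5% level)."""
    from scipy.stats import linregress
    best = np.inf
    for y in series:
        y = np.asarray(y, float)
        good = y > 0
        if good.sum() < 3:
            continue
        fit = linregress(times[good], np.log(y[good]))
        if fit.pvalue > 0.05:
            continue
        best = min(best, 0.10 / abs(fit.slope))
    return best


def check_timescales(traj: Trajectory, config: RunConfig | None = None,
                     margin_m: float = 10.0, margin_v: float = 3.0,
                     run_doubling: bool = True) -> TimescaleReport:
    """Evaluate the tau_m << tau_inf << tau_VD conditions with margins.

    Also runs the doubling check: the inference is repeated at twice the
    window length and the maximum relative change of the windowed (k, D)
    medians is reported; changes above 20% indicate the window is not in
    the quasi-static regime.  All problems surface as flags, never errors.
    """
    config = config or RunConfig()
    base = sliding_window_inference(traj, config)
    d_bar = float(np.median(base.diffusivity))
    # robust confinement size: twice the 95th-percentile radial distance
    # from the centre of mass (the bounding box is outlier-dominated)
    com = traj.positions.mean(axis=0)
    radii = np.linalg.norm(traj.positions - com, axis=1)
    l_conf = 2.0 * float(np.quantile(radii, 0.95))
    tau_m = l_conf ** 2 / d_bar
    # window length needed to reach the target mean occupancy
    mesh = build_mesh(traj, config.mesh_factor)
    counts = occupancy_counts(traj, mesh)
    rate = np.mean(list(counts.values())) / traj.duration
    tau_req = config.min_points_per_cell / rate
    tau_vd = _empirical_tau_vd(base.times, [base.k, base.diffusivity])
    doubling = None
    if run_doubling and 2 * config.window_length <= traj.duration:
        doubled = sliding_window_inference(
            traj, replace_window(config, 2 * config.window_length))
        changes = []
        for a, b in ((np.median(base.k), np.median(doubled.k)),
                     (np.median(base.diffusivity), np.median(doubled.diffusivity))):
            changes.append(abs(b - a) / abs(a))
        doubling = float(max(changes))
    return TimescaleReport(
        tau_m=tau_m, tau_inf=config.window_length, tau_inf_required=tau_req,
        tau_vd=tau_vd,
        mixing_ok=config.window_length >= margin_m * tau_m,
        variation_ok=tau_vd >= margin_v * config.window_length,
        occupancy_ok=config.window_length >= tau_req,
        doubling_max_rel_change=doubling)


def replace_window(config: RunConfig, window_length: float) -> RunConfig:
    return replace(config, window_length=window_length)


# -------------------------------------------------- harmonic calibration

@dataclass(frozen=True)
class HarmonicCalibration:
    """Inferred-vs-input map for windowed harmonic (k, D) estimates.

    At frame intervals comparable to the confinement relaxation time
    1/(k D), the per-step Gaussian likelihood systematically inflates the
    inferred spring constant and deflates the inferred diffusivity; the
    effect is deterministic, so it is compensated by inverting a
    calibration curve built from simulated stationary harmonic fixtures
    spanning the relevant (k, D) range.
    """

    k_input: np.ndarray
    d_input: np.ndarray
    k_inferred: np.ndarray     # monotone along the path
    d_inferred: np.ndarray

    def correct(self, k_hat, d_hat):
        k = np.interp(k_hat, self.k_inferred, self.k_input)
        d = np.interp(d_hat, self.d_inferred, self.d_input)
        return k, d


def _monotone(y: np.ndarray) -> np.ndarray:
    """Non-decreasing least-squares projection (pool adjacent violators)."""
    from .hopping import _isotonic
    return _isotonic(np.asarray(y, float))


def build_harmonic_calibration(pairs, frame_dt: float,
                               window_length: float = 40.0,
                               replicates: int = 4, seed: int = 0,
                               config: RunConfig | None = None,
                               substeps: int = 10) -> HarmonicCalibration:
    """Simulate stationary harmonic fixtures at each (k, D) pair and
    record the mean windowed estimates.

    ``pairs`` must be ordered so that k decreases and D increases along
    the path (the relaxation direction of the enzyme schedules); the
    recorded curves are monotonised before inversion.
    """
    from .potentials import HarmonicWell
    from .simulate import simulate

    config = config or RunConfig()
    n_frames = int(round(window_length / frame_dt))
    k_in, d_in, k_out, d_out = [], [], [], []
    for j, (k, d) in enumerate(pairs):
        ks, ds = [], []
        for r in range(replicates):
            traj = simulate(HarmonicWell(k=k, ndim=2), d, n_frames=n_frames,
                            frame_dt=frame_dt, substeps=substeps,
                            seed=np.random.SeedSequence([seed, j, r]))
            res = infer_map(traj, config)
            fit = fit_harmonic(res)
            if fit.confined:
                ks.append(fit.k)
                ds.append(average_diffusivity(res))
        k_in.append(k)
        d_in.append(d)
        k_out.append(float(np.mean(ks)))
        d_out.append(float(np.mean(ds)))
    order = np.argsort(k_in)
    k_in = np.asarray(k_in)[order]
    k_out = _monotone(np.asarray(k_out)[order])
    order_d = np.argsort(d_in)
    d_in = np.asarray(d_in)[order_d]
    d_out = _monotone(np.asarray(d_out)[order_d])
    return HarmonicCalibration(k_input=k_in, d_input=d_in,
                               k_inferred=k_out, d_inferred=d_out)


def apply_harmonic_calibration(result: WindowedResult,
                               calibration: HarmonicCalibration
                               ) -> WindowedResult:
    """Windowed series with (k, D) passed through the calibration inverse."""
    k, d = calibration.correct(result.k, result.diffusivity)
    return replace(result, k=np.asarray(k), diffusivity=np.asarray(d))
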