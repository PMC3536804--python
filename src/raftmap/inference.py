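"""MAP inference of diffusivity and potential fields from one trajectory.

The trajectory's bounding box is divided into square mesh cells of side
``mesh_factor`` times the mean displacement (default 2), so a step stays
in its cell or reaches a neighbour.  Within each cell the potential
gradient is taken constant (evaluated at the cell centre) and the
diffusivity is a free per-cell parameter; the potential itself is a
single polynomial of order C expanded about the trajectory's centre of
mass.  The per-step transition density is the short-time Gaussian
solution of the Fokker--Planck equation with localisation noise folded
into the variance:

    r_{mu+1} | r_mu  ~  N( r_mu - D_c grad(V)(x_c) dt,
                           2 (D_c + sigma^2/dt) dt  per axis )

with k_BT = 1.  With a flat prior the posterior is the product of these
densities over all steps grouped by cell, and the MAP point is found by
quasi-Newton ascent over (polynomial coefficients, log per-cell D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import ConvexHull, Delaunay

from .trajectory import RunConfig, Trajectory, summarize

__all__ = [
    "Mesh",
    "PotentialModel",
    "DiffusivityField",
    "InferenceResult",
    "HarmonicFit",
    "build_mesh",
    "basis_index",
    "basis_exponents",
    "transition_logprob",
    "log_posterior",
    "infer_map",
    "fit_harmonic",
    "average_diffusivity",
    "potential_minima",
]


# ---------------------------------------------------------------- mesh

@dataclass(frozen=True)
class Mesh:
    """Regular square grid over the trajectory bounding box (+1 cell margin)."""

    origin: np.ndarray          # (d,) lower corner in um
    cell_size: float            # um
    shape: tuple[int, ...]      # cells per axis
    ndim: int

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index of each point (C order)."""
        p = np.atleast_2d(np.asarray(points, float))
        idx = np.floor((p - self.origin) / self.cell_size).astype(int)
        for ax, n in enumerate(self.shape):
            if np.any(idx[:, ax] < 0) or np.any(idx[:, ax] >= n):
                raise ValueError("point outside mesh")
        return np.ravel_multi_index(tuple(idx[:, ax] for ax in range(self.ndim)),
                                    self.shape)

    def centers(self, flat: np.ndarray) -> np.ndarray:
        idx = np.column_stack(np.unravel_index(np.asarray(flat, int), self.shape))
        return self.origin + (idx + 0.5) * self.cell_size

    def multi_index(self, flat: np.ndarray) -> np.ndarray:
        return np.column_stack(np.unravel_index(np.asarray(flat, int), self.shape))


def build_mesh(traj: Trajectory, mesh_factor: float = 2.0) -> Mesh:
    """Square cells of ``mesh_factor`` x mean step length, one-cell margin."""
    if traj.n_steps < 2:
        raise ValueError("need at least 2 steps to build a mesh")
    mean_step = float(np.mean(
        np.linalg.norm(traj.steps[traj.valid_steps], axis=1)))
    if mean_step <= 0:
        raise ValueError("degenerate (zero-extent) trajectory")
    h = mesh_factor * mean_step
    lo = traj.positions.min(axis=0) - h
    hi = traj.positions.max(axis=0) + h
    shape = tuple(int(math.ceil((hi[ax] - lo[ax]) / h)) or 1
                  for ax in range(traj.ndim))
    return Mesh(origin=lo, cell_size=h, shape=shape, ndim=traj.ndim)


def occupancy_counts(traj: Trajectory, mesh: Mesh) -> dict[int, int]:
    """Transition counts N_(i,j): steps whose start point lies in the cell."""
    ci = mesh.cell_of(traj.positions[:-1][traj.valid_steps])
    cells, counts = np.unique(ci, return_counts=True)
    return dict(zip(cells.tolist(), counts.tolist()))


# ----------------------------------------------------------- polynomial

def basis_index(l: int, m: int) -> int:
    """Flat index k = (l+m)(l+m+1)/2 + l of the 2D monomial x^l y^m."""
    if l < 0 or m < 0:
        raise ValueError("degrees must be non-negative")
    s = l + m
    return s * (s + 1) // 2 + l


def basis_exponents(order: int, ndim: int) -> np.ndarray:
    """Exponent table, row k -> (l, m), for all monomials of total degree <= order."""
    if ndim == 1:
        return np.column_stack([np.arange(order + 1), np.zeros(order + 1, int)])
    n = (order + 1) * (order + 2) // 2
    out = np.zeros((n, 2), int)
    for s in range(order + 1):
        for l in range(s + 1):
            out[basis_index(l, s - l)] = (l, s - l)
    return out


@dataclass(frozen=True)
class PotentialModel:
    """Polynomial potential about the trajectory centre of mass.

    Coefficients are stored against scaled coordinates u = (r - center)/scale
    for numerical conditioning; ``coefficients_um`` converts back to the
    k_BT um^-(l+m) convention.  The constant term is gauge: it is excluded
    from optimisation and set afterwards so the minimum over visited cells
    is zero.
    """

    order: int
    center: np.ndarray          # (d,)
    scale: float
    coef: np.ndarray            # scaled-coordinate coefficients, index k
    ndim: int

    @property
    def exponents(self) -> np.ndarray:
        return basis_exponents(self.order, self.ndim)

    @property
    def coefficients_um(self) -> np.ndarray:
        exp = self.exponents
        return self.coef / self.scale ** (exp[:, 0] + exp[:, 1])

    def _design(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        u = (p - self.center) / self.scale
        exp = self.exponents
        phi = u[:, 0][:, None] ** exp[:, 0]
        if self.ndim == 2:
            phi = phi * u[:, 1][:, None] ** exp[:, 1]
        return phi

    def value(self, points: np.ndarray) -> np.ndarray:
        return self._design(points) @ self.coef

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """grad(V) in k_BT/um, shape (n, d)."""
        p = np.atleast_2d(np.asarray(points, float))
        u = (p - self.center) / self.scale
        exp = self.exponents
        l, m = exp[:, 0], exp[:, 1]
        out = np.zeros_like(p)
        ux = u[:, 0][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            dx = np.where(l > 0, l * ux ** np.maximum(l - 1, 0), 0.0)
        if self.ndim == 2:
            uy = u[:, 1][:, None]
            dx = dx * uy ** m
            dy = np.where(m > 0, m * uy ** np.maximum(m - 1, 0), 0.0) * ux ** l
            out[:, 1] = dy @ self.coef / self.scale
        out[:, 0] = dx @ self.coef / self.scale
        return out

    def hessian(self, point: np.ndarray) -> np.ndarray:
        """Second-derivative matrix at one point, k_BT/um^2."""
        eps = 1e-4
        p = np.asarray(point, float).reshape(1, -1)
        h = np.zeros((self.ndim, self.ndim))
        for a in range(self.ndim):
            for b in range(self.ndim):
                pp = p.copy(); pp[0, a] += eps; pp[0, b] += eps
                pm = p.copy(); pm[0, a] += eps; pm[0, b] -= eps
                mp = p.copy(); mp[0, a] -= eps; mp[0, b] += eps
                mm = p.copy(); mm[0, a] -= eps; mm[0, b] -= eps
                h[a, b] = (self.value(pp) - self.value(pm)
                           - self.value(mp) + self.value(mm))[0] / (4 * eps * eps)
        return h

    def with_offset(self, delta: float) -> "PotentialModel":
        coef = self.coef.copy()
        coef[0] += delta
        return replace(self, coef=coef)


# -------------------------------------------------------------- fields

@dataclass(frozen=True)
class DiffusivityField:
    """Per-cell diffusivity estimates with provenance.

    ``estimated`` marks cells whose D was a free likelihood parameter;
    sparsely visited cells inherit the value of the nearest estimated
    cell instead of overfitting a nearly unconstrained parameter.
    """

    cells: np.ndarray           # flat cell indices, sorted
    values: np.ndarray          # D in um^2/s
    estimated: np.ndarray       # bool
    counts: np.ndarray          # transition counts per cell

    def __post_init__(self):
        if np.any(self.values <= 0):
            raise ValueError("diffusivities must be positive")

    def value_at(self, flat_cells: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.cells, flat_cells)
        if np.any(pos >= self.cells.size) or np.any(self.cells[pos] != flat_cells):
            raise ValueError("cell without a diffusivity value")
        return self.values[pos]


@dataclass(frozen=True)
class InferenceResult:
    potential: PotentialModel
    dfield: DiffusivityField
    sigma: float
    mesh: Mesh
    log_posterior: float
    diagnostics: dict = field(compare=False)
    positions: np.ndarray = field(compare=False, repr=False)

    @property
    def cell_potential(self) -> np.ndarray:
        """Potential value at each occupied cell centre (gauge: min = 0)."""
        return self.potential.value(self.mesh.centers(self.dfield.cells))

    def to_dict(self) -> dict:
        exp = self.potential.exponents
        return {
            "potential": {
                "order": int(self.potential.order),
                "ndim": int(self.potential.ndim),
                "center_um": self.potential.center.tolist(),
                "scale_um": float(self.potential.scale),
                "exponents": exp.tolist(),
                "coefficients_kBT_per_um": self.potential.coefficients_um.tolist(),
            },
            "diffusivity": {
                "cells": self.mesh.multi_index(self.dfield.cells).tolist(),
                "values_um2_s": self.dfield.values.tolist(),
                "provenance": ["estimated" if e else "inherited"
                               for e in self.dfield.estimated],
                "counts": self.dfield.counts.tolist(),
            },
            "sigma_um": float(self.sigma),
            "mesh": {"origin_um": self.mesh.origin.tolist(),
                     "cell_size_um": float(self.mesh.cell_size),
                     "shape": list(self.mesh.shape)},
            "log_posterior": float(self.log_posterior),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if not isinstance(v, np.ndarray)},
        }


# ---------------------------------------------------------- likelihood

def transition_logprob(r0, r1, dt: float, d_cell: float, grad_v,
                       sigma: float = 0.0) -> float:
    """Log-density of one recorded step under the local Gaussian propagator.

    Mean displacement is the deterministic drift -D grad(V) dt; the
    per-axis variance 2 (D + sigma^2/dt) dt combines thermal diffusion
    and static localisation noise.
    """
    if dt <= 0 or d_cell <= 0:
        raise ValueError("dt and D must be positive")
    r0 = np.atleast_1d(np.asarray(r0, float))
    r1 = np.atleast_1d(np.asarray(r1, float))
    g = np.atleast_1d(np.asarray(grad_v, float))
    var = 2.0 * (d_cell + sigma ** 2 / dt) * dt
    e = r1 - r0 + d_cell * g * dt
    return float(-0.5 * r0.size * math.log(2.0 * math.pi * var)
                 - np.sum(e ** 2) / (2.0 * var))


def log_posterior(traj: Trajectory, mesh: Mesh, potential: PotentialModel,
                  dfield: DiffusivityField, sigma: float,
                  gradient_at: str = "cell_center") -> float:
    """Sum of per-step log transition densities over cells.

    With a flat prior this is the log posterior up to an additive
    constant; it is invariant under V -> V + c because only the gradient
    enters.  ``gradient_at`` selects where the polynomial gradient is
    evaluated: frozen at the cell centre, or at each step's start point.
    """
    ok = traj.valid_steps
    r0 = traj.positions[:-1][ok]
    dr = traj.steps[ok]
    dt = traj.dt[ok]
    ci = mesh.cell_of(r0)
    d_step = dfield.value_at(ci)
    where = mesh.centers(ci) if gradient_at == "cell_center" else r0
    grad = potential.gradient(where)
    var = 2.0 * (d_step + sigma ** 2 / dt) * dt
    e = dr + d_step[:, None] * grad * dt[:, None]
    d = traj.ndim
    return float(-0.5 * d * np.sum(np.log(2.0 * np.pi * var))
                 - np.sum(np.sum(e ** 2, axis=1) / (2.0 * var)))


# ------------------------------------------------------------- MAP fit

def _prepare(traj: Trajectory, config: RunConfig):
    mesh = build_mesh(traj, config.mesh_factor)
    r0 = traj.positions[:-1][traj.valid_steps]
    ci_flat = mesh.cell_of(r0)
    cells, ic, counts = np.unique(ci_flat, return_inverse=True,
                                  return_counts=True)
    est = counts >= config.min_transitions_estimate
    if not est.any():
        est = counts == counts.max()
    centers = mesh.centers(cells)
    # inherited cells borrow the parameter of the nearest estimated cell
    est_idx = np.flatnonzero(est)
    param_of_cell = np.empty(cells.size, int)
    param_of_cell[est_idx] = np.arange(est_idx.size)
    if (~est).any():
        d2 = np.sum((centers[~est][:, None, :] - centers[est_idx][None, :, :]) ** 2,
                    axis=2)
        param_of_cell[np.flatnonzero(~est)] = np.argmin(d2, axis=1)
    return mesh, cells, ic, counts, est, param_of_cell, centers


def _negative_logpost_factory(traj, config, mesh, cells, ic, counts, est,
                              param_of_cell, centers, order):
    ok = traj.valid_steps
    dr = traj.steps[ok]
    dt = traj.dt[ok]
    d = traj.ndim
    sig2 = config.sigma ** 2
    com = traj.positions.mean(axis=0)
    spread = float(np.sqrt(np.mean(np.sum((traj.positions - com) ** 2, axis=1))))
    scale = max(spread, 1e-3)
    exp = basis_exponents(order, d)
    l, m = exp[:, 0], exp[:, 1]
    nk = exp.shape[0]
    r0 = traj.positions[:-1][ok]
    where = centers[ic] if config.gradient_at == "cell_center" else r0
    u = (where - com) / scale
    # basis gradient per step w.r.t. physical coords: (n_steps, d, nk-1)
    ux = u[:, 0][:, None]
    with np.errstate(divide="ignore"):
        gx = np.where(l > 0, l * ux ** np.maximum(l - 1, 0), 0.0)
    if d == 2:
        uy = u[:, 1][:, None]
        gx = gx * uy ** m
        gy = np.where(m > 0, m * uy ** np.maximum(m - 1, 0), 0.0) * ux ** l
        g_full = np.stack([gx, gy], axis=1) / scale
    else:
        g_full = gx[:, None, :] / scale
    g_free = np.ascontiguousarray(g_full[:, :, 1:])  # constant term excluded
    nfree = nk - 1
    n_params = int(est.sum())
    pi_step = param_of_cell[ic]                    # per-step D parameter index
    two_dt = 2.0 * dt
    sig_term = sig2 / dt

    def negloglik(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            a = theta[:nfree]
            d_param = np.exp(np.clip(theta[nfree:], -25.0, 25.0))
            d_step = d_param[pi_step]
            ga = g_free @ a                        # (n_steps, d)
            e = dr + (d_step * dt)[:, None] * ga
            v = two_dt * (d_step + sig_term)
            sq = np.sum(e * e, axis=1)
            f = (0.5 * d * np.sum(np.log(2.0 * np.pi * v))
                 + 0.5 * np.sum(sq / v))
            if not np.isfinite(f):                 # wild restart excursion
                return 1e300, np.zeros_like(theta)
            # gradient wrt coefficients
            w = d_step * dt / v
            grad_a = np.einsum("sdk,sd->k", g_free, w[:, None] * e)
            # gradient wrt log D
            q = (d * dt / v + np.sum(e * ga, axis=1) * dt / v
                 - sq * dt / (v * v))
            grad_d = (np.bincount(pi_step, weights=q, minlength=n_params)
                      * d_param)
        return f, np.concatenate([grad_a, grad_d])

    return negloglik, nfree, n_params, com, scale, exp


def _fit_once(traj, config, order):
    mesh, cells, ic, counts, est, param_of_cell, centers = _prepare(traj, config)
    nll, nfree, n_params, com, scale, exp = _negative_logpost_factory(
        traj, config, mesh, cells, ic, counts, est, param_of_cell, centers, order)
    stats = summarize(traj, sigma=config.sigma)
    d0 = max(stats["apparent_diffusivity_um2_s"]
             - stats["noise_diffusivity_um2_s"], 1e-4)
    theta0 = np.concatenate([np.zeros(nfree), np.full(n_params, math.log(d0))])
    rng = np.random.default_rng(config.seed)
    best = None
    n_iter = 0
    converged = False
    starts = [theta0]
    for _ in range(config.n_restarts):
        pert = theta0.copy()
        pert[:nfree] += rng.normal(0.0, 0.5, nfree)
        pert[nfree:] += rng.normal(0.0, 0.3, n_params)
        starts.append(pert)
    for s in starts:
        res = optimize.minimize(nll, s, jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12,
                                         "gtol": 1e-8})
        n_iter += res.nit
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    a_full = np.concatenate([[0.0], theta[:nfree]])
    model = PotentialModel(order=order, center=com, scale=scale,
                           coef=a_full, ndim=traj.ndim)
    # gauge: minimum over visited cell centres is zero
    v_cells = model.value(centers)
    model = model.with_offset(-float(v_cells.min()))
    d_param = np.exp(theta[nfree:])
    dfield = DiffusivityField(cells=cells, values=d_param[param_of_cell],
                              estimated=est, counts=counts)
    diag = {
        "converged": converged,
        "iterations": int(n_iter),
        "restarts": int(config.n_restarts),
        "order": int(order),
        "neg_log_posterior": float(best.fun),
        "init_diffusivity": float(d0),
        "n_estimated_cells": int(est.sum()),
        "n_inherited_cells": int((~est).sum()),
        "mean_occupancy": float(counts.mean()),
    }
    result = InferenceResult(potential=model, dfield=dfield, sigma=config.sigma,
                             mesh=mesh, log_posterior=-float(best.fun),
                             diagnostics=diag, positions=traj.positions)
    return result


def infer_map(traj: Trajectory, config: RunConfig | None = None) -> InferenceResult:
    """Joint MAP estimate of the polynomial potential and per-cell diffusivities.

    The fit starts at order ``config.polynomial_order`` (default 4) and is
    redone at order 6 when the two lowest detected minima are farther
    apart than ``config.order_escalation_distance`` (large-separation
    hopping needs the extra flexibility).  Occupancy below
    ``min_points_per_cell`` on average only warns via diagnostics.
    """
    config = config or RunConfig()
    result = _fit_once(traj, config, config.polynomial_order)
    if config.polynomial_order < 6:
        minima = potential_minima(result)
        if len(minima) >= 2:
            sep = float(np.linalg.norm(np.asarray(minima[0][0])
                                       - np.asarray(minima[1][0])))
            if sep > config.order_escalation_distance:
                result = _fit_once(traj, config, 6)
                result.diagnostics["order_escalated"] = True
    if result.diagnostics["mean_occupancy"] < config.min_points_per_cell:
        result.diagnostics["low_occupancy_warning"] = True
    return result


# ----------------------------------------------------------- summaries

@dataclass(frozen=True)
class HarmonicFit:
    k: float                    # mean principal curvature, k_BT/um^2
    center: np.ndarray
    principal_curvatures: np.ndarray
    confined: bool


def fit_harmonic(result: InferenceResult) -> HarmonicFit:
    """Occupancy-weighted quadratic fit of the inferred potential.

    Fits V ~ 1/2 (r-r0)^T H (r-r0) at the visited cell centres and
    reports the mean of the principal curvatures as the spring constant.
    A non-confined (non-positive-curvature) landscape is flagged.
    """
    centers = result.mesh.centers(result.dfield.cells)
    v = result.potential.value(centers)
    w = np.sqrt(result.dfield.counts.astype(float))
    d = centers.shape[1]
    if d == 1:
        x = centers[:, 0]
        design = np.column_stack([x ** 2, x, np.ones_like(x)])
    else:
        x, y = centers[:, 0], centers[:, 1]
        design = np.column_stack([x ** 2, y ** 2, x * y, x, y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(design * w[:, None], v * w, rcond=None)
    if d == 1:
        h = np.array([[2.0 * sol[0]]])
        b = np.array([sol[1]])
    else:
        h = np.array([[2.0 * sol[0], sol[2]], [sol[2], 2.0 * sol[1]]])
        b = sol[3:5]
    eig = np.linalg.eigvalsh(h)
    confined = bool(np.all(eig > 0))
    center = (np.linalg.solve(h, -b) if confined
              else np.full(d, np.nan))
    return HarmonicFit(k=float(eig.mean()), center=center,
                       principal_curvatures=eig, confined=confined)


def average_diffusivity(result: InferenceResult) -> float:
    """Occupancy-weighted mean D over estimated (not inherited) cells."""
    est = result.dfield.estimated
    if not est.any():
        raise ValueError("no estimated cells")
    w = result.dfield.counts[est].astype(float)
    return float(np.average(result.dfield.values[est], weights=w))


# ------------------------------------------------------ minima search

def _hull_mask(points, grid_pts):
    """Boolean mask of grid points inside the convex hull of the data."""
    if points.shape[1] == 1:
        lo, hi = points.min(), points.max()
        return (grid_pts[:, 0] >= lo) & (grid_pts[:, 0] <= hi)
    try:
        hull = ConvexHull(points)
        tri = Delaunay(points[hull.vertices])
    except Exception:
        return np.ones(grid_pts.shape[0], bool)
    return tri.find_simplex(grid_pts) >= 0


def potential_minima(result: InferenceResult, pitch: float = 0.005
                     ) -> list[tuple[np.ndarray, float]]:
    """Local minima of the inferred potential inside the visited hull.

    The polynomial is evaluated on a regular grid of pitch <= 5 nm
    restricted to the convex hull of the trajectory points; local minima
    separated by at least one mesh cell are returned sorted by value.
    Minima on the hull boundary are discarded (a monotone landscape has
    no interior minimum).
    """
    pts = result.positions
    d = pts.shape[1]
    pitch = min(pitch, result.mesh.cell_size / 4.0)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    axes = [np.arange(lo[ax], hi[ax] + pitch, pitch) for ax in range(d)]
    if d == 1:
        grid_pts = axes[0][:, None]
        shape = (axes[0].size,)
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
        shape = gx.shape
    inside = _hull_mask(pts, grid_pts)
    v = np.full(grid_pts.shape[0], np.inf)
    v[inside] = result.potential.value(grid_pts[inside])
    v = v.reshape(shape)
    inside = inside.reshape(shape)
    # minima must beat everything within one mesh cell
    size = max(3, 2 * int(round(result.mesh.cell_size / pitch)) + 1)
    vmin = ndimage.minimum_filter(v, size=size, mode="nearest")
    interior = ndimage.binary_erosion(inside, iterations=1, border_value=0)
    cand = (v == vmin) & interior & np.isfinite(v)
    idx = np.argwhere(cand)
    minima = [(grid_pts.reshape(shape + (d,))[tuple(i)], v[tuple(i)])
              for i in idx]
    minima.sort(key=lambda t: t[1])
    # merge duplicates closer than one mesh cell, keeping the lowest
    kept: list[tuple[np.ndarray, float]] = []
    for pos, val in minima:
        if all(np.linalg.norm(pos - p) >= result.mesh.cell_size
               for p, _ in kept):
            kept.append((pos, val))
    return kept
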