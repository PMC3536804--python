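"""Boltzmann statistics of inferred potentials.

With the potential in k_BT units (beta = 1), the occupancy probability is
P(r) = exp(-V(r)) / Z with Z the partition function over the integration
domain, and the free energy is F = -log Z.  Because the inference fixes
the potential only up to an additive constant, F carries the same gauge
freedom: only differences between states evaluated under the same gauge
convention (minimum of V equal to zero here) and over comparable domains
are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inference import InferenceResult

__all__ = ["FreeEnergyResult", "boltzmann_map", "free_energy", "delta_F",
           "harmonic_free_energy"]


@dataclass(frozen=True)
class FreeEnergyResult:
    z: float                     # partition function (um^d measure)
    f: float                     # free energy, k_BT
    domain: tuple                # ((lo, hi), ...) per axis, um
    pitch: float                 # um
    convergence: float           # |dF| under pitch halving, k_BT
    ndim: int


def _as_callable(potential):
    if isinstance(potential, InferenceResult):
        return potential.potential.value, potential.potential.ndim
    if hasattr(potential, "value"):
        return potential.value, potential.ndim
    raise TypeError("potential must be an InferenceResult or expose .value")


def _default_domain(result: InferenceResult):
    """Visited hull bounding box plus a one-cell margin."""
    lo = result.positions.min(axis=0) - result.mesh.cell_size
    hi = result.positions.max(axis=0) + result.mesh.cell_size
    return tuple((float(a), float(b)) for a, b in zip(lo, hi))


def _grid_values(value, domain, pitch):
    axes = [np.arange(lo, hi + pitch / 2, pitch) for lo, hi in domain]
    if len(axes) == 1:
        pts = axes[0][:, None]
        shape = (axes[0].size,)
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        shape = gx.shape
    return axes, value(pts).reshape(shape)


def _integrate(value, domain, pitch):
    axes, v = _grid_values(value, domain, pitch)
    if np.min(v) < -50.0:
        raise ValueError("potential unbounded below on domain: exp(-V) diverges")
    w = np.exp(-v)
    z = np.trapezoid(w, axes[0], axis=0)
    if len(axes) == 2:
        z = np.trapezoid(z, axes[1], axis=0)
    return float(z)


def boltzmann_map(potential, domain=None, pitch: float | None = None):
    """Normalised occupancy probability P = exp(-V)/Z on a regular grid.

    Returns (axes, P) where P is the grid of probability densities; the
    Riemann sum of P times the cell area is 1.
    """
    value, ndim = _as_callable(potential)
    if domain is None:
        if not isinstance(potential, InferenceResult):
            raise ValueError("an explicit domain is required for a bare potential")
        domain = _default_domain(potential)
    if pitch is None:
        pitch = min((hi - lo) for lo, hi in domain) / 200.0
    axes, v = _grid_values(value, domain, pitch)
    if np.min(v) < -50.0:
        raise ValueError("potential unbounded below on domain: exp(-V) diverges")
    w = np.exp(-v)
    cell = pitch ** ndim
    return axes, w / (w.sum() * cell)


def free_energy(potential, domain=None, pitch: float | None = None,
                gauge_min_zero: bool = True) -> FreeEnergyResult:
    """F = -log Z with Z evaluated by trapezoidal quadrature.

    Convergence is verified by halving the pitch; the reported
    ``convergence`` is the resulting change in F.  With
    ``gauge_min_zero`` the potential is shifted so its minimum over the
    domain is zero before integration (the inference gauge).
    """
    value, ndim = _as_callable(potential)
    if domain is None:
        if not isinstance(potential, InferenceResult):
            raise ValueError("an explicit domain is required for a bare potential")
        domain = _default_domain(potential)
    if pitch is None:
        pitch = min((hi - lo) for lo, hi in domain) / 200.0
    shift = 0.0
    if gauge_min_zero:
        _, v = _grid_values(value, domain, pitch)
        shift = float(np.min(v))
    shifted = (lambda pts: value(pts) - shift)
    z1 = _integrate(shifted, domain, pitch)
    z2 = _integrate(shifted, domain, pitch / 2.0)
    f1, f2 = -math.log(z1), -math.log(z2)
    if not math.isfinite(f2):
        raise ValueError("non-convergent quadrature")
    return FreeEnergyResult(z=z2, f=f2, domain=tuple(domain), pitch=pitch / 2.0,
                            convergence=abs(f2 - f1), ndim=ndim)


def delta_F(before, after, domain=None, pitch: float | None = None) -> float:
    """Free-energy change F_after - F_before under a shared convention.

    Both states are re-gauged to minimum zero and integrated over the
    same domain (the union of their visited domains by default), so the
    difference measures the change in confinement entropy.
    """
    _, nd_b = _as_callable(before)
    _, nd_a = _as_callable(after)
    if nd_b != nd_a:
        raise ValueError("states have mismatched dimensionality")
    if domain is None:
        if not (isinstance(before, InferenceResult)
                and isinstance(after, InferenceResult)):
            raise ValueError("an explicit domain is required for bare potentials")
        db = _default_domain(before)
        da = _default_domain(after)
        domain = tuple((min(b[0], a[0]), max(b[1], a[1]))
                       for b, a in zip(db, da))
    fb = free_energy(before, domain=domain, pitch=pitch)
    fa = free_energy(after, domain=domain, pitch=pitch)
    return fa.f - fb.f


def harmonic_free_energy(k: float, ndim: int = 2) -> float:
    """Closed form for V = 1/2 k |r|^2 over all space: Z = (2 pi / k)^(d/2),
    so F = (d/2) log(k / 2 pi).  Useful as a surrogate when a confining
    state is summarised by its harmonic spring constant."""
    if k <= 0:
        raise ValueError("k must be positive")
    return 0.5 * ndim * math.log(k / (2.0 * math.pi))
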