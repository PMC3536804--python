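"""Potential and diffusivity field specifications for the Langevin simulator.

All energies are in units of k_BT, lengths in micrometres, so a potential
value of 3 means 3 k_BT and spring constants carry k_BT/um^2.  Every form
provides a vectorised ``value`` for analysis code and scalar ``grad1`` /
``grad2`` evaluators used in the tight integrator loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Potential",
    "HarmonicWell",
    "QuarticDoubleWell",
    "PolynomialPotential",
    "HarmonicWellFreeExterior",
    "RoughOverlay",
    "RegionDiffusivity",
    "FieldSchedule",
    "make_double_well",
    "make_enzyme_schedule",
    "ENZYME_PRESETS",
]


class Potential:
    """Base class: a continuously differentiable energy landscape."""

    ndim: int = 2

    def value(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def grad1(self, x: float) -> float:  # pragma: no cover
        raise NotImplementedError

    def grad2(self, x: float, y: float) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class HarmonicWell(Potential):
    """V(r) = 1/2 k |r - center|^2."""

    k: float
    center: tuple[float, ...] = (0.0, 0.0)
    ndim: int = 2

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("spring constant must be non-negative")

    def value(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(self.center[: self.ndim])
        return 0.5 * self.k * np.sum((p - c) ** 2, axis=1)

    def grad1(self, x):
        return self.k * (x - self.center[0])

    def grad2(self, x, y):
        return self.k * (x - self.center[0]), self.k * (y - self.center[1])


@dataclass(frozen=True)
class QuarticDoubleWell(Potential):
    """Symmetric quartic double well V(x) = E_h ((x/b)^2 - 1)^2.

    Minima sit at x = +-b with V = 0 and the barrier at x = 0 has the
    analytic height E_h.  In 2D a harmonic confinement 1/2 lateral_k y^2
    is added along the transverse axis.
    """

    e_h: float
    b: float
    lateral_k: float = 0.0
    ndim: int = 1

    def __post_init__(self):
        if self.e_h < 0:
            raise ValueError("barrier height E_h must be non-negative")
        if self.b <= 0:
            raise ValueError("half-separation b must be positive")

    @property
    def barrier_height(self) -> float:
        return self.e_h

    def value(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        x = p[:, 0]
        v = self.e_h * ((x / self.b) ** 2 - 1.0) ** 2
        if self.ndim == 2:
            v = v + 0.5 * self.lateral_k * p[:, 1] ** 2
        return v

    def grad1(self, x):
        return 4.0 * self.e_h * x * ((x / self.b) ** 2 - 1.0) / self.b ** 2

    def grad2(self, x, y):
        return (4.0 * self.e_h * x * ((x / self.b) ** 2 - 1.0) / self.b ** 2,
                self.lateral_k * y)


@dataclass(frozen=True)
class PolynomialPotential(Potential):
    """Monomial expansion about a center, coefficients in k_BT um^-(l+m).

    ``exponents`` is a sequence of (l, m) pairs (m ignored in 1D) and
    ``coefficients`` the matching a_k values.
    """

    exponents: tuple
    coefficients: tuple
    center: tuple[float, ...] = (0.0, 0.0)
    ndim: int = 2

    def value(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        x = p[:, 0] - self.center[0]
        y = p[:, 1] - self.center[1] if self.ndim == 2 else None
        v = np.zeros(p.shape[0])
        for (l, m), a in zip(self.exponents, self.coefficients):
            term = a * x ** l
            if self.ndim == 2:
                term = term * y ** m
            v += term
        return v

    def grad1(self, x):
        u = x - self.center[0]
        g = 0.0
        for (l, _m), a in zip(self.exponents, self.coefficients):
            if l > 0:
                g += a * l * u ** (l - 1)
        return g

    def grad2(self, x, y):
        u = x - self.center[0]
        w = y - self.center[1]
        gx = gy = 0.0
        for (l, m), a in zip(self.exponents, self.coefficients):
            if l > 0:
                gx += a * l * u ** (l - 1) * w ** m
            if m > 0:
                gy += a * m * u ** l * w ** (m - 1)
        return gx, gy


def _hermite(t, v1, s1, v2, s2, w):
    """Cubic Hermite value/slope on t in [0, 1] over physical width w."""
    h00 = 2 * t ** 3 - 3 * t ** 2 + 1
    h10 = t ** 3 - 2 * t ** 2 + t
    h01 = -2 * t ** 3 + 3 * t ** 2
    h11 = t ** 3 - t ** 2
    val = h00 * v1 + h10 * w * s1 + h01 * v2 + h11 * w * s2
    d00 = 6 * t ** 2 - 6 * t
    d10 = 3 * t ** 2 - 4 * t + 1
    d01 = -6 * t ** 2 + 6 * t
    d11 = 3 * t ** 2 - 2 * t
    slope = (d00 * v1 + d01 * v2) / w + d10 * s1 + d11 * s2
    return val, slope


@dataclass(frozen=True)
class HarmonicWellFreeExterior(Potential):
    """Harmonic well matched to a flat exterior plateau.

    Inside radius R the well is harmonic with k = 2 E_h / R^2 so the rim
    energy equals the escape barrier E_h; outside, the potential is the
    constant plateau E_h (free motion).  The junction is smoothed over
    ``smooth_width`` with a C1 cubic blend, so the force vanishes
    continuously at the rim.
    """

    e_h: float
    radius: float
    smooth_width: float = 0.010
    center: tuple[float, ...] = (0.0, 0.0)
    ndim: int = 2

    def __post_init__(self):
        if self.e_h < 0:
            raise ValueError("escape barrier must be non-negative")
        if not 0 < self.smooth_width < self.radius:
            raise ValueError("smooth_width must be in (0, radius)")

    @property
    def k(self) -> float:
        return 2.0 * self.e_h / self.radius ** 2

    def _profile(self, r: float) -> tuple[float, float]:
        """Radial value and slope."""
        r1 = self.radius - self.smooth_width
        if r <= r1:
            return 0.5 * self.k * r * r, self.k * r
        if r >= self.radius:
            return self.e_h, 0.0
        t = (r - r1) / self.smooth_width
        return _hermite(t, 0.5 * self.k * r1 * r1, self.k * r1,
                        self.e_h, 0.0, self.smooth_width)

    def value(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        c = np.asarray(self.center[: self.ndim])
        r = np.sqrt(np.sum((p - c) ** 2, axis=1))
        return np.array([self._profile(ri)[0] for ri in r])

    def grad1(self, x):
        u = x - self.center[0]
        r = abs(u)
        _, s = self._profile(r)
        return s if u >= 0 else -s

    def grad2(self, x, y):
        u, w = x - self.center[0], y - self.center[1]
        r = math.hypot(u, w)
        if r < 1e-12:
            return 0.0, 0.0
        _, s = self._profile(r)
        return s * u / r, s * w / r


class RoughOverlay(Potential):
    """Base potential plus frozen Gaussian roughness on a fine grid.

    The roughness is realised as i.i.d. Gaussian values of standard
    deviation ``sigma_v`` (k_BT) on a regular grid of pitch
    ``corr_length`` with (bi)linear interpolation between nodes, making
    the amplitude and correlation length well defined.  Small-scale
    roughness of amplitude sigma_v reduces the apparent long-time
    diffusivity by approximately exp(-(sigma_v/k_BT)^2) (rough-potential
    slowdown).
    """

    #: grid nodes per correlation length; fine enough that interpolation
    #: does not dilute the stationary variance of the field
    OVERSAMPLE = 5

    def __init__(self, base: Potential, sigma_v: float, extent: float,
                 corr_length: float = 0.020, seed: int | None = None):
        if sigma_v < 0:
            raise ValueError("sigma_v must be non-negative")
        from scipy.ndimage import gaussian_filter, gaussian_filter1d
        self.base = base
        self.sigma_v = float(sigma_v)
        self.corr_length = float(corr_length)
        self.extent = float(extent)
        self.ndim = base.ndim
        rng = np.random.default_rng(seed)
        self._pitch = corr_length / self.OVERSAMPLE
        n = int(math.ceil(2 * extent / self._pitch)) + 2
        self._x0 = -extent
        if self.ndim == 1:
            white = rng.standard_normal(n)
            vals = gaussian_filter1d(white, self.OVERSAMPLE, mode="wrap")
        else:
            white = rng.standard_normal((n, n))
            vals = gaussian_filter(white, self.OVERSAMPLE, mode="wrap")
        vals -= vals.mean()
        sd = float(vals.std())
        self._vals = vals * (sigma_v / sd if sd > 0 else 0.0)
        if self.ndim == 1:
            self._slopes = np.diff(self._vals) / self._pitch
        self._n = n

    def _idx(self, u: float) -> tuple[int, float]:
        s = (u - self._x0) / self._pitch
        i = int(s)
        i = min(max(i, 0), self._n - 2)
        return i, s - i

    def value(self, points):
        p = np.atleast_2d(np.asarray(points, float))
        out = self.base.value(p).copy()
        for j in range(p.shape[0]):
            if self.ndim == 1:
                i, f = self._idx(p[j, 0])
                out[j] += self._vals[i] * (1 - f) + self._vals[i + 1] * f
            else:
                i, f = self._idx(p[j, 0])
                k, g = self._idx(p[j, 1])
                v = self._vals
                out[j] += ((1 - f) * (1 - g) * v[i, k] + f * (1 - g) * v[i + 1, k]
                           + (1 - f) * g * v[i, k + 1] + f * g * v[i + 1, k + 1])
        return out

    def grad1(self, x):
        i, _ = self._idx(x)
        return self.base.grad1(x) + self._slopes[i]

    def grad2(self, x, y):
        gx, gy = self.base.grad2(x, y)
        i, f = self._idx(x)
        k, g = self._idx(y)
        v = self._vals
        ell = self._pitch
        rx = ((1 - g) * (v[i + 1, k] - v[i, k]) + g * (v[i + 1, k + 1] - v[i, k + 1])) / ell
        ry = ((1 - f) * (v[i, k + 1] - v[i, k]) + f * (v[i + 1, k + 1] - v[i + 1, k])) / ell
        return gx + rx, gy + ry


@dataclass(frozen=True)
class RegionDiffusivity:
    """Piecewise-constant diffusivity: d_in inside a disc, d_out outside.

    Evaluated at the current position (Ito convention, no spurious-drift
    term), matching the per-subdomain locally constant diffusivity of the
    inference likelihood.
    """

    d_in: float
    d_out: float
    radius: float
    center: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self):
        if self.d_in <= 0 or self.d_out <= 0:
            raise ValueError("diffusivities must be positive")

    def at1(self, x: float) -> float:
        return self.d_in if abs(x - self.center[0]) < self.radius else self.d_out

    def at2(self, x: float, y: float) -> float:
        r = math.hypot(x - self.center[0], y - self.center[1])
        return self.d_in if r < self.radius else self.d_out


@dataclass(frozen=True)
class FieldSchedule:
    """Slowly varying harmonic confinement: (k, D) interpolated between knots.

    Emulates minutes-scale enzymatic relaxation of the confinement: the
    spring constant and diffusivity follow piecewise-linear paths through
    the knot values.  ``tau_vd`` is the characteristic field-variation
    time: the smallest spacing between consecutive knots across which any
    parameter changes by more than 10 percent.
    """

    knot_times: tuple
    k_values: tuple
    d_values: tuple
    center: tuple[float, float] = (0.0, 0.0)
    ndim: int = 2

    def __post_init__(self):
        t = np.asarray(self.knot_times, float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing, >= 2 knots")
        if len(self.k_values) != t.size or len(self.d_values) != t.size:
            raise ValueError("knot arrays must share length")
        if np.any(np.asarray(self.k_values) < 0) or np.any(np.asarray(self.d_values) <= 0):
            raise ValueError("k must be >= 0 and D > 0 at every knot")

    @property
    def duration(self) -> float:
        return float(self.knot_times[-1] - self.knot_times[0])

    def k_at(self, t):
        return np.interp(t, self.knot_times, self.k_values)

    def d_at(self, t):
        return np.interp(t, self.knot_times, self.d_values)

    @property
    def tau_vd(self) -> float:
        t = np.asarray(self.knot_times, float)
        best = math.inf
        for arr in (np.asarray(self.k_values, float), np.asarray(self.d_values, float)):
            rel = np.abs(np.diff(arr)) / np.maximum(np.minimum(arr[:-1], arr[1:]), 1e-300)
            spans = np.diff(t)[rel > 0.10]
            if spans.size:
                best = min(best, float(spans.min()))
        return best


def make_double_well(e_h: float, half_separation: float, dim: int = 1,
                     lateral_k: float | None = None) -> QuarticDoubleWell:
    """Quartic double well with minima at +-half_separation and barrier e_h.

    In 2D, harmonic confinement of stiffness ``lateral_k`` is added along
    the transverse axis.
    """
    if dim not in (1, 2):
        raise ValueError("dim must be 1 or 2")
    if dim == 2 and (lateral_k is None or lateral_k < 0):
        raise ValueError("2D double well needs a non-negative lateral_k")
    return QuarticDoubleWell(e_h=e_h, b=half_separation,
                             lateral_k=lateral_k or 0.0, ndim=dim)


# Endpoint (k in k_BT/um^2, D in um^2/s) presets mimicking the measured
# relaxation of raft confinement under cholesterol oxidase (CHOx) and
# sphingomyelinase (SMase): stiff/slow initially, loose/fast at the end.
ENZYME_PRESETS = {
    "CHOx": {"k": (237.0, 35.4), "D": (0.063, 0.18)},
    "SMase": {"k": (206.0, 10.5), "D": (0.066, 0.27)},
}


def make_enzyme_schedule(kind: str, duration: float,
                         window_length: float = 40.0) -> FieldSchedule:
    """Monotone (k, D) relaxation schedule emulating enzyme treatment.

    ``duration`` must be at least 10 window lengths so that sliding-window
    inference has a comfortable separation between the window length and
    the field-variation time.
    """
    if kind not in ENZYME_PRESETS:
        raise ValueError(f"unknown schedule kind {kind!r}; use CHOx or SMase")
    if duration < 10.0 * window_length:
        raise ValueError("schedule duration must be >= 10 x window_length")
    p = ENZYME_PRESETS[kind]
    return FieldSchedule(knot_times=(0.0, float(duration)),
                         k_values=p["k"], d_values=p["D"])
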