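"""Attached-state energy landscape and inter-well hopping rates.

The strongly attached head moves on a three-well landscape: the central
region is a sinusoid of barrier ``H`` (5.8 KT) tilted by the ATP bias
``F_atp = 8 KT / d``, so consecutive minima drop by exactly 8 KT.  Following
the construction used for the model, each minimum is rendered as a parabola
of stiffness ``kappa_well`` (48 pN/nm) and the convex inter-well humps as
cubic polynomials with matching value and slope (C1 everywhere).  A constant
phase ``alpha_d`` shifts the first minimum to the extension at attachment,
``x0``.

Because ``kappa_well`` is much stiffer than the motor elastic element
(``kappa_m`` = 2 pN/nm), the conformational coordinate is adiabatically
pinned at well bottoms and the continuous landscape reduces to a 3-state
hopping process with Kramers rates

    r = nu_attempt * exp(-dE_barrier / KT)

where the barrier is measured on the *total* energy (landscape plus
``kappa_m x^2 / 2`` elastic term).  Forward/backward rates then satisfy
detailed balance exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, ParameterError

__all__ = [
    "StrokeGeometry",
    "stroke_geometry",
    "LandscapeSpec",
    "build_landscape",
    "total_energy",
    "hop_rates",
]

# Rates below nu*exp(-_DE_CUT_KT) are treated as zero.
_DE_CUT_KT = 30.0


@dataclass(frozen=True)
class StrokeGeometry:
    """Barrier constants of one power-stroke step (shared by both steps).

    ``barrier_fwd`` is the landscape-only barrier from a minimum to the next
    saddle in the stroke direction (decreasing x); ``a`` is the distance from
    the minimum to that saddle along x.  The backward barrier is
    ``barrier_fwd + bias`` and the backward saddle offset is ``d - a``.
    """

    barrier_fwd: float   # pN nm
    a: float             # nm
    d: float             # nm
    bias: float          # pN nm, energy drop per step (8 KT)


def stroke_geometry(params: ModelParameters) -> StrokeGeometry:
    """Closed-form extrema of ``H sin(2 pi x / d + alpha) + F_atp x``.

    Stationary points satisfy ``cos(theta) = -F_atp d / (2 pi H)``; the
    maximum (saddle) carries ``sin > 0`` and the minimum ``sin < 0``.  The
    tilt both lowers the forward barrier below ``2H`` and pulls the saddle
    slightly closer than half a period.
    """
    if params.h <= 0 or params.d <= 0:
        raise ParameterError("H and d must be strictly positive")
    c0 = params.bias_kt / (2.0 * math.pi * params.h_kt)
    if c0 >= 1.0:
        raise ParameterError("ATP tilt exceeds the sinusoidal barrier slope")
    theta_max = math.acos(-c0)               # saddle phase, sin > 0
    theta_min = 2.0 * math.pi - theta_max    # minimum phase, sin < 0
    a = params.d * (theta_min - theta_max) / (2.0 * math.pi)
    barrier = (
        params.h * (math.sin(theta_max) - math.sin(theta_min))
        - params.f_atp * a
    )
    return StrokeGeometry(
        barrier_fwd=barrier, a=a, d=params.d, bias=params.bias_kt * params.kt
    )


@dataclass
class LandscapeSpec:
    """Piecewise C1 landscape: parabolic wells + cubic connectors.

    ``segments`` is a list of ``(lo, hi, coeffs)`` with ``coeffs`` the
    polynomial coefficients (numpy order, highest power first) valid on
    ``lo <= x < hi``; segments are contiguous and ordered by decreasing x
    (the stroke direction).
    """

    x0: float
    minima: np.ndarray           # well positions (x0, x0-d, x0-2d)
    well_energies: np.ndarray    # (0, -8KT, -16KT), pN nm
    saddles: np.ndarray          # saddle positions, len 2
    saddle_energies: np.ndarray  # pN nm
    segments: list[tuple[float, float, np.ndarray]]
    kappa_well: float
    kt: float

    def energy(self, x: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the landscape (pN nm); pure and deterministic."""
        xa = np.asarray(x, dtype=float)
        out = np.empty_like(xa)
        flat = xa.ravel()
        res = out.ravel()
        for i, xi in enumerate(flat):
            res[i] = self._energy_scalar(xi)
        return out if out.ndim else float(out)

    def _energy_scalar(self, x: float) -> float:
        # walls: continue the outermost parabolas beyond the three wells
        if x >= self.segments[0][1]:
            return 0.5 * self.kappa_well * (x - self.minima[0]) ** 2
        if x < self.segments[-1][0]:
            return self.well_energies[2] + 0.5 * self.kappa_well * (
                x - self.minima[2]
            ) ** 2
        for lo, hi, coeffs in self.segments:
            if lo <= x < hi:
                return float(np.polyval(coeffs, x))
        # hi of the first segment is inclusive at the top wall boundary
        lo, hi, coeffs = self.segments[0]
        return float(np.polyval(coeffs, x))


def _hermite_cubic(xa: float, ya: float, sa: float,
                   xb: float, yb: float, sb: float) -> np.ndarray:
    """Cubic through (xa, ya) and (xb, yb) with slopes sa, sb."""
    h = xb - xa
    a = np.array([
        [xa**3, xa**2, xa, 1.0],
        [xb**3, xb**2, xb, 1.0],
        [3 * xa**2, 2 * xa, 1.0, 0.0],
        [3 * xb**2, 2 * xb, 1.0, 0.0],
    ])
    if abs(h) < 1e-12:
        raise ParameterError("degenerate connector segment")
    return np.linalg.solve(a, np.array([ya, yb, sa, sb]))


def build_landscape(x0: float, params: ModelParameters) -> LandscapeSpec:
    """Construct the three-well landscape with its first minimum at ``x0``."""
    geo = stroke_geometry(params)
    kt = params.kt
    kw = params.kappa_well
    d = params.d
    bias = geo.bias

    minima = np.array([x0, x0 - d, x0 - 2 * d])
    e_min = np.array([0.0, -bias, -2 * bias])
    saddles = minima[:2] - geo.a
    e_sad = e_min[:2] + geo.barrier_fwd

    # Parabolic half-width: keep the parabola comfortably below the saddle
    # so the connectors have room to turn over (C1 cubic Hermite pieces).
    w = min(0.35 * d, math.sqrt(geo.barrier_fwd / kw))

    segments: list[tuple[float, float, np.ndarray]] = []
    top = minima[0] + w

    def well_poly(k: int) -> np.ndarray:
        # 0.5*kw*(x - xm)^2 + e  ->  standard coeffs
        xm, e = minima[k], e_min[k]
        return np.array([0.5 * kw, -kw * xm, 0.5 * kw * xm**2 + e])

    for k in range(3):
        lo_w, hi_w = minima[k] - w, minima[k] + w if k > 0 else top
        segments.append((minima[k] - w, minima[k] + w if k else top,
                         well_poly(k)))
        if k < 2:
            xa = minima[k] - w          # right junction of the hump
            xs = saddles[k]
            xb = minima[k + 1] + w      # left junction of the hump
            ya = e_min[k] + 0.5 * kw * w**2
            yb = e_min[k + 1] + 0.5 * kw * w**2
            if not (xb < xs < xa):
                raise ParameterError("saddle outside connector span")
            up = _hermite_cubic(xs, e_sad[k], 0.0, xa, ya, -kw * w)
            down = _hermite_cubic(xb, yb, kw * w, xs, e_sad[k], 0.0)
            segments.append((xs, xa, up))
            segments.append((xb, xs, down))

    # order by decreasing x and make spans contiguous/exclusive
    segments.sort(key=lambda s: -s[0])
    return LandscapeSpec(
        x0=x0, minima=minima, well_energies=e_min,
        saddles=saddles, saddle_energies=e_sad,
        segments=segments, kappa_well=kw, kt=kt,
    )


def total_energy(
    well: int, x_ext: float, spec: LandscapeSpec, params: ModelParameters
) -> float:
    """Well energy plus the motor elastic energy at extension ``x_ext``."""
    if well not in (0, 1, 2):
        raise ParameterError(f"invalid well index {well}")
    return float(spec.well_energies[well]) + 0.5 * params.kappa_m * x_ext**2


def hop_rates(
    well: int, x_ext: float, params: ModelParameters
) -> tuple[float, float]:
    """Kramers rates (forward, backward) for an attached motor.

    A forward hop advances the stroke coordinate by ``d`` and therefore
    *raises* the elastic extension by ``d`` (Huxley-Simmons recovery); the
    saddle sits at extension ``x_ext + a``, so the barrier is the
    total-energy difference between the current well bottom (at ``x_ext``)
    and that saddle.  Backward hops see the saddle at ``x_ext - (d - a)``.
    A negative barrier (strain-assisted, barrierless hop) caps the rate at
    ``nu_attempt``; the ratio of any forward/backward pair obeys detailed
    balance by construction.
    """
    if well not in (0, 1, 2):
        raise ParameterError(f"invalid well index {well}")
    geo = stroke_geometry(params)
    nu, kt, km = params.nu_attempt, params.kt, params.kappa_m
    b = geo.d - geo.a

    def rate(de: float) -> float:
        if de <= 0.0:
            return nu
        if de > _DE_CUT_KT * kt:
            return 0.0
        return nu * math.exp(-de / kt)

    fwd = 0.0
    if well < 2:
        de_f = geo.barrier_fwd + km * geo.a * (0.5 * geo.a + x_ext)
        fwd = rate(de_f)
    bwd = 0.0
    if well > 0:
        de_b = geo.barrier_fwd + geo.bias + km * b * (0.5 * b - x_ext)
        bwd = rate(de_b)
    return fwd, bwd


def dump_landscape(
    spec: LandscapeSpec, path, n: int = 2000, pad: float = 2.0
) -> None:
    """Write (x, E) samples to CSV for plotting/validation."""
    x = np.linspace(spec.minima[2] - pad, spec.minima[0] + pad, n)
    e = spec.energy(x)
    np.savetxt(path, np.column_stack([x, e]), delimiter=",",
               header="x_nm,energy_pNnm", comments="")
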