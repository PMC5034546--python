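"""State-transition rate functions.

These are the pure scalar/vector forms of the hazards used by the engine
kernel: the tension-dependent mechanosensing factor ``ON_f``, the thin
filament nearest-neighbour cooperativity ``gamma**n`` of the conventional
wiring, and the Huxley-1957 strain-dependent attachment/detachment laws
with mechanical dislodging beyond ``x_dislodge``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, ParameterError

__all__ = [
    "RateContext",
    "on_factor",
    "off_on_rates",
    "attach_rate",
    "detach_rate",
    "check_dislodge",
]


@dataclass(frozen=True)
class RateContext:
    """Inputs to the OFF/ON gate for one motor.

    ``t_rel`` is the instantaneous thick-filament tension over the
    calibrated plateau tension T0, clamped at zero from below;
    ``n_neighbors`` counts axially adjacent crowns that are weakly or
    strongly attached (ON or any S state).
    """

    t_rel: float = 0.0
    n_neighbors: int = 0
    x: float = 0.0
    model_kind: str = "ms"

    def __post_init__(self):
        if self.n_neighbors not in (0, 1, 2):
            raise ParameterError("n_neighbors must be 0, 1 or 2")


def on_factor(t_rel, m: float, t_f: float):
    """Mechanosensing factor ON_f(T) = m + (1-m) exp(-t_f / T_rel**2).

    Monotonically increasing in tension, bounded in [m, 1): the floor ``m``
    is the zero-tension limit (a relaxed thick filament keeps only a small
    fraction of motors switching ON) and the factor saturates toward 1 as
    the filament is loaded.  ``t_f = 0`` is the sentinel that disables
    mechanosensing (ON_f identically 1).  Negative tensions are clamped.
    """
    if not 0 < m < 1:
        raise ParameterError("0 < m < 1 required")
    if t_f < 0:
        raise ParameterError("t_f >= 0 required")
    t = np.clip(np.asarray(t_rel, dtype=float), 0.0, None)
    if t_f == 0.0:
        out = np.ones_like(t)
    else:
        with np.errstate(divide="ignore"):
            out = np.where(
                t > 0.0, m + (1.0 - m) * np.exp(-t_f / np.where(t > 0, t, 1.0) ** 2), m
            )
    return float(out) if np.isscalar(t_rel) else out


def off_on_rates(
    ctx: RateContext, params: ModelParameters
) -> tuple[float, float]:
    """(k01, k10) for a detached motor in the given context.

    Mechanosensing wiring: ``(k01_0 * ON_f(T_rel), k10_0)``.
    Conventional wiring: ``(k01_0 * gamma**n, k10_0 * gamma**-n)``.
    """
    kind = ctx.model_kind
    if kind == "ms":
        return (
            params.k01_0 * on_factor(ctx.t_rel, params.m, params.t_f),
            params.k10_0,
        )
    if kind == "conventional":
        g = params.gamma ** ctx.n_neighbors
        return params.k01_0 * g, params.k10_0 / g
    raise ParameterError(f"unknown model_kind {kind!r}")


def attach_rate(x, params: ModelParameters):
    """H57 attachment hazard: ``f1 * x`` on the window ``(0, x_lim]``.

    Zero for non-stretched configurations (x <= 0) and, following the
    classic convention, zero again beyond ``x_lim``.
    """
    xa = np.asarray(x, dtype=float)
    out = np.where((xa > 0.0) & (xa <= params.x_lim), params.f1 * xa, 0.0)
    return float(out) if np.isscalar(x) else out


def detach_rate(x, params: ModelParameters):
    """H57 detachment hazard from any attached state.

    ``g1 * x`` for stretched motors (x > 0); the large constant ``g2`` for
    x <= 0 (the boundary is assigned to the fast branch).  The destination
    state -- ON in the mechanosensing wiring, OFF in the conventional one --
    is the engine's business; one ATP is consumed either way.
    """
    xa = np.asarray(x, dtype=float)
    out = np.where(xa > 0.0, params.g1 * xa, params.g2)
    return float(out) if np.isscalar(x) else out


def check_dislodge(x, params: ModelParameters):
    """True where ``|x|`` exceeds the forced-detachment strain (20 nm)."""
    xa = np.asarray(x, dtype=float)
    out = np.abs(xa) > params.x_dislodge
    return bool(out) if np.isscalar(x) else out


def dump_rate_table(params: ModelParameters, path, x_max: float = 22.0,
                    n: int = 441) -> None:
    """Write the strain grid of attach/detach hazards to CSV."""
    x = np.linspace(-x_max, x_max, n)
    table = np.column_stack([
        x, attach_rate(x, params), detach_rate(x, params),
        check_dislodge(x, params).astype(float),
    ])
    np.savetxt(path, table, delimiter=",",
               header="x_nm,attach_per_s,detach_per_s,dislodge", comments="")
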