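"""Shared measurement helpers for the test suite."""

from __future__ import annotations

import numpy as np

from halfsarc.analysis import fit_exp_with_delay, plateau_level
from halfsarc.engine import Trace


def fit_rise(trace: Trace):
    """Plateau-normalised delayed-exponential fit of an activation rise."""
    plat = plateau_level(trace)
    return fit_exp_with_delay((trace.t, trace.tension / plat),
                              plateau_fixed=1.0), plat


def fit_recovery_tau(trace: Trace, switch_s: float):
    """Fit the isometric recovery from the mode-switch instant."""
    plat = plateau_level(trace)
    return fit_exp_with_delay(
        (trace.t, trace.tension / plat),
        window=(switch_s, float(trace.t[-1])), plateau_fixed=1.0)


def atp_rate_tail(trace: Trace, tail_s: float = 0.2) -> float:
    """ATP/myosin/s over the final ``tail_s`` of a trace."""
    i0 = int(np.searchsorted(trace.t, trace.t[-1] - tail_s))
    dt = trace.t[-1] - trace.t[i0]
    return float((trace.atp[-1] - trace.atp[i0]) / (trace.n_motors * dt))


def clamp_velocity(trace: Trace, steady_frac: float = 0.6) -> float:
    """Shortening velocity (nm/ms) over the steady phase of a load clamp."""
    n = trace.t.size
    sl = slice(int((1 - steady_frac) * n), n)
    return float(-np.polyfit(trace.t[sl], trace.z[sl], 1)[0] * 1e-3)
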