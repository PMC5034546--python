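"""Programmatic test inputs: synthetic traces and hand-checkable ensembles.

Nothing here touches the network or the filesystem; every fixture is
deterministic given its seed, so golden values in the test suite are
reproducible bit for bit.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .engine import Trace, seed_rng_state
from .geometry import HalfSarcomereState, build_lattice
from .params import OFF, ON, S0, S1, S2, STATE_NAMES, ModelParameters, ParameterError

__all__ = ["make_exp_trace", "make_micro_ensemble"]

_STATE_INDEX = {name: i for i, name in enumerate(STATE_NAMES)}


def make_exp_trace(
    tau_ms: float,
    delay_ms: float,
    plateau: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_ms: float = 300.0,
    dt_ms: float = 0.2,
    t0: float = 1.0,
) -> Trace:
    """Sampled delayed-exponential tension trace with Gaussian noise.

    Ground truth is recorded in ``trace.meta['truth']``.
    """
    if tau_ms <= 0:
        raise ParameterError("tau must be positive")
    t = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms) * 1e-3
    t_ms = t * 1e3
    y = np.zeros_like(t)
    mask = t_ms >= delay_ms
    y[mask] = plateau * (1.0 - np.exp(-(t_ms[mask] - delay_ms) / tau_ms))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    zeros = np.zeros(t.size)
    izeros = np.zeros(t.size, dtype=np.int64)
    return Trace(
        t=t, tension=y * t0, z=zeros,
        n_off=izeros, n_on=izeros, n_s0=izeros, n_s1=izeros, n_s2=izeros,
        atp=izeros,
        meta={
            "t0": t0, "n_fil": 1, "n_motors": 1,
            "truth": {"tau_ms": tau_ms, "delay_ms": delay_ms,
                      "plateau": plateau, "noise_sd": noise_sd},
        },
    )


def make_micro_ensemble(
    params: ModelParameters,
    states: Sequence[str],
    strains: Sequence[float | None] | None = None,
    z: float = 0.0,
    seed: int = 0,
) -> HalfSarcomereState:
    """Minimal single-filament state for hand-verified mechanics tests.

    ``states`` names one motor each ('OFF', 'ON', 'S0', 'S1', 'S2');
    ``strains`` gives the elastic extension of each attached motor (and must
    be None/omitted for detached ones).
    """
    n = len(states)
    if strains is None:
        strains = [None] * n
    if len(strains) != n:
        raise ParameterError("states and strains must have equal length")
    p = params.replace(n_fil=1, n_xb=max(n, 1))
    st = build_lattice(p, seed=seed)
    st.rng_state = seed_rng_state(seed)
    st.z = z
    for j, (name, x) in enumerate(zip(states, strains)):
        if name not in _STATE_INDEX:
            raise ParameterError(f"unknown state {name!r}")
        code = _STATE_INDEX[name]
        st.state[0, j] = code
        if code >= S0:
            if x is None:
                raise ParameterError(f"attached motor {j} needs a strain")
            st.cc[0, j] = x - z
            st.x0[0, j] = x
        elif x is not None:
            raise ParameterError(f"detached motor {j} must not have a strain")
    return st
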