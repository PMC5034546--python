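"""Pre-built simulation protocols and their runners.

Each builder returns a :class:`Protocol`: an ordered list of boundary
condition segments plus an initial condition.  The protocols mirror the
standard fibre experiments the model is meant to reproduce: isometric
tetanus rise, tension recovery after 20/40 ms of unloaded shortening,
force-velocity load clamps, and the Lombardi conditioning/test double-step
paradigm.  ``run`` executes a protocol reproducibly from
``(params, protocol, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import (
    RAMP_FROM_ZERO, RAMP_FULL, RAMP_INACTIVE,
    Segment, Trace, run_segments,
)
from .geometry import HalfSarcomereState, build_lattice
from .params import ModelParameters, ParameterError

__all__ = [
    "Protocol",
    "isometric_activation",
    "relaxed",
    "release_restretch",
    "load_clamp_fv",
    "double_step",
    "run",
    "prepare_plateau",
]

INITIAL_CONDITIONS = ("all_OFF", "relaxed_equilibrium", "tetanus_plateau")


@dataclass(frozen=True)
class Protocol:
    id: str
    segments: tuple[Segment, ...]
    initial_condition: str = "all_OFF"
    active: bool = True          # thin-filament activation on/off

    def __post_init__(self):
        if self.initial_condition not in INITIAL_CONDITIONS:
            raise ParameterError(
                f"unknown initial condition {self.initial_condition!r}")
        if not self.segments:
            raise ParameterError("protocol needs at least one segment")
        for s in self.segments:
            if s.duration_ms < 0:
                raise ParameterError("segment durations must be >= 0")

    @property
    def duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "initial_condition": self.initial_condition,
            "active": self.active,
            "segments": [
                {"duration_ms": s.duration_ms, "mode": s.mode,
                 "dz": s.dz, "load_rel": s.load_rel}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            id=d["id"],
            initial_condition=d.get("initial_condition", "all_OFF"),
            active=d.get("active", True),
            segments=tuple(Segment(**s) for s in d["segments"]),
        )


def isometric_activation(duration_ms: float = 400.0) -> Protocol:
    """Tension rise at fixed length from the resting state.

    At rest almost all motors are OFF (the gate equilibrium keeps ~5% ON);
    thin-filament activation ramps in over the first millisecond and the
    ensemble tension rises monotonically (on average) to the tetanus
    plateau, which defines T0.
    """
    return Protocol(
        id="isometric_activation",
        segments=(Segment(duration_ms, "length"),),
        initial_condition="relaxed_equilibrium",
    )


def relaxed(duration_ms: float = 1000.0) -> Protocol:
    """Resting muscle: no thin-filament activation, OFF/ON gate only."""
    return Protocol(
        id="relaxed",
        segments=(Segment(duration_ms, "length"),),
        initial_condition="all_OFF",
        active=False,
    )


def release_restretch(
    t_zero_load_ms: float, recovery_ms: float = 300.0
) -> Protocol:
    """Zero-load shortening for ``t_zero_load_ms`` then isometric recovery.

    From the tetanus plateau the load is clamped to zero (the fibre shortens
    at its maximum velocity, ~5% of length over 20 ms, ~10% over 40 ms);
    length control then holds whatever z was reached and the tension
    recovers to the plateau.
    """
    if t_zero_load_ms < 0:
        raise ParameterError("t_zero_load_ms must be >= 0")
    segs = []
    if t_zero_load_ms > 0:
        segs.append(Segment(t_zero_load_ms, "load", load_rel=0.0))
    segs.append(Segment(recovery_ms, "length"))
    return Protocol(
        id=f"release_restretch_{t_zero_load_ms:g}ms",
        segments=tuple(segs),
        initial_condition="tetanus_plateau",
    )


def load_clamp_fv(
    loads: Sequence[float], duration_ms: float = 150.0
) -> list[Protocol]:
    """Load-clamp family for the force-velocity curve.

    Each protocol clamps one relative load in [0, 1) from the tetanus
    plateau; the shortening velocity is the negative slope of z(t) over the
    steady phase.
    """
    out = []
    for load in loads:
        if not 0.0 <= load < 1.0:
            raise ParameterError(f"load {load} outside [0, 1)")
        out.append(Protocol(
            id=f"load_clamp_{load:g}",
            segments=(Segment(duration_ms, "load", load_rel=load),),
            initial_condition="tetanus_plateau",
        ))
    return out


def double_step(
    conditioning_nm: float = 5.0,
    test_nm: float = 2.0,
    delays_ms: Sequence[float] = (2.0, 4.0, 8.0, 14.0),
    pre_ms: float = 10.0,
    post_ms: float = 50.0,
) -> list[Protocol]:
    """Lombardi conditioning/test paradigm: two shortening steps.

    A conditioning release (default 5 nm per half-sarcomere) is followed,
    after each delay, by a test release (default 2 nm); the tension
    recovered after the test step grows with the delay as the power-stroke
    ensemble re-equilibrates.
    """
    out = []
    for delay in delays_ms:
        if delay <= 0:
            raise ParameterError("delays must be positive")
        out.append(Protocol(
            id=f"double_step_{delay:g}ms",
            segments=(
                Segment(pre_ms, "length"),
                Segment(delay, "length", dz=-abs(conditioning_nm)),
                Segment(post_ms, "length", dz=-abs(test_nm)),
            ),
            initial_condition="tetanus_plateau",
        ))
    return out


def relaxed_state(params: ModelParameters, seed: int) -> HalfSarcomereState:
    """Resting-muscle state: OFF/ON gate at its zero-tension equilibrium.

    A relaxed fibre keeps a small fraction of motors in the ON
    (disordered-relaxed) state -- about 5% with the reference parameters --
    set by the detailed balance ``m k01_0 / (m k01_0 + k10_0)`` of the gate
    at zero thick-filament tension.  Each motor is drawn ON with that
    probability (seeded, reproducible).
    """
    from .params import ON
    state = build_lattice(params, seed=seed)
    if params.model_kind == "ms":
        num = params.m * params.k01_0
    else:
        num = params.k01_0
    p_on = num / (num + params.k10_0)
    rng = np.random.default_rng((seed * 2654435761 + 17) % (2**31))
    on = rng.random(state.state.shape) < p_on
    state.state[on] = ON
    return state


def prepare_plateau(
    params: ModelParameters, seed: int, duration_ms: float = 400.0
) -> HalfSarcomereState:
    """Run an activation to the tetanus plateau and return the state.

    The returned snapshot can be passed to :func:`run` as ``initial_state``
    to amortise the plateau preparation across protocol variants.
    """
    state = relaxed_state(params, seed)
    run_segments(state, [Segment(duration_ms, "length")], params,
                 seed=seed, ramp_mode=RAMP_FROM_ZERO, record=False)
    return state


def run(
    protocol: Protocol,
    params: ModelParameters,
    seed: int,
    initial_state: HalfSarcomereState | None = None,
    plateau_prep_ms: float = 400.0,
) -> tuple[Trace, HalfSarcomereState]:
    """Execute a protocol; returns ``(trace, final_state)``.

    The protocol clock starts at zero and the ATP counter is reset at entry,
    so energetics windows refer to the recorded trace alone.  Fully
    reproducible from ``(params, protocol, seed)``; passing
    ``initial_state`` (e.g. a shared plateau snapshot) re-seeds the stream
    with ``seed`` and skips the preparation phase.
    """
    if initial_state is not None:
        state = initial_state.copy()
    elif protocol.initial_condition == "tetanus_plateau":
        state = prepare_plateau(params, seed, plateau_prep_ms)
    elif protocol.initial_condition == "relaxed_equilibrium":
        state = relaxed_state(params, seed)
    else:
        state = build_lattice(params, seed=seed)

    state.t = 0.0
    state.atp_count = 0
    if not protocol.active:
        ramp = RAMP_INACTIVE
    elif protocol.initial_condition == "all_OFF":
        ramp = RAMP_FROM_ZERO
    else:
        ramp = RAMP_FULL
    trace = run_segments(state, protocol.segments, params,
                         seed=seed + 0x5A17, ramp_mode=ramp)
    trace.meta["protocol_id"] = protocol.id
    trace.meta["seed"] = seed
    return trace, state
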