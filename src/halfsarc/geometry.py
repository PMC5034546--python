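"""Half-sarcomere lattice construction and the mutable simulation state.

The modelling unit is a half-sarcomere with ``n_fil`` rigid thick/thin
filament couples sharing one sliding coordinate ``z`` through the Z-line
(``z = 0`` is the optimal length; shortening decreases ``z``).  Each thick
filament carries ``n_xb`` myosin heads; a head is either packed on the
backbone (OFF), detached but available (ON), or strongly attached in one of
three wells of the power-stroke landscape (S0, S1, S2).

Sign convention: ``x`` is the extension of the motor elastic element, so the
force a head exerts on its filament is ``kappa_m * x`` (pN).  For an attached
head ``x = C + z`` where the constant ``C`` absorbs the attachment origin and
the well index; half-sarcomere shortening (decreasing z) therefore relaxes
attached heads, while each forward power-stroke hop re-stretches them by
``d`` -- the Huxley-Simmons tension-recovery mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import OFF, ON, S0, S1, S2, STATE_NAMES, ModelParameters, ParameterError

__all__ = [
    "MotorRecord",
    "HalfSarcomereState",
    "crown_positions",
    "build_lattice",
    "heads_per_actin_3d",
]


def crown_positions(lm: float, lb: float, crown_spacing: float) -> np.ndarray:
    """Axial positions of myosin crowns on [LB, LM], one every crown spacing.

    With the reference geometry (LM=825, LB=50, spacing=14.3 nm) this yields
    the familiar ~54 myosin molecules per half-thick filament.
    """
    if crown_spacing <= 0:
        raise ParameterError("crown_spacing must be positive")
    if lm < lb:
        raise ParameterError("LM must not be below LB")
    n = int(np.floor((lm - lb) / crown_spacing))
    return lb + crown_spacing * (1.0 + np.arange(n))


def heads_per_actin_3d(
    n_molecules: int = 54, n_thin_neighbors: int = 6, n_sharing: int = 3
) -> float:
    """Myosin molecules interacting with one thin filament in the 3-D lattice.

    Each thick filament distributes ``n_molecules`` among its
    ``n_thin_neighbors`` surrounding thin filaments, and each thin filament
    is served by ``n_sharing`` thick filaments: 54 * 3 / 6 = 27.  The 2-D
    simplification deliberately raises the per-actin head count to
    ``n_xb = 76`` to allow for interactions from additional heads.
    """
    if n_thin_neighbors <= 0 or n_sharing <= 0:
        raise ParameterError("neighbour and sharing counts must be positive")
    return n_molecules * n_sharing / n_thin_neighbors


@dataclass
class MotorRecord:
    """Read-only snapshot of a single myosin head."""

    state: str                 # one of OFF, ON, S0, S1, S2
    x: float | None            # elastic extension, nm (None when detached)
    x0: float | None           # extension at the time of attachment, nm
    anchor: float              # axial anchor position on the thick filament
    well: int | None           # 0/1/2 for S0/S1/S2, None when detached

    @property
    def attached(self) -> bool:
        return self.well is not None


@dataclass
class HalfSarcomereState:
    """Mutable ensemble state: motor arrays, sliding coordinate, bookkeeping.

    Arrays are laid out ``(n_fil, n_xb)``.  ``cc`` is the per-motor affine
    constant such that ``x = cc + z`` for attached motors (NaN otherwise);
    ``phi`` is the fixed candidate-binding-site phase in ``[0, site_period)``.
    """

    state: np.ndarray          # int8 (n_fil, n_xb)
    cc: np.ndarray             # float64, x = cc + z when attached
    x0: np.ndarray             # float64, extension at attachment (NaN else)
    phi: np.ndarray            # float64, site phase
    anchors: np.ndarray        # float64 (n_xb,)
    z: float = 0.0
    t: float = 0.0
    atp_count: int = 0
    t0: float = 1.0            # reference plateau tension per filament, pN
    kappa_m: float = 2.0
    starved: bool = False
    rng_state: np.ndarray = field(
        default_factory=lambda: np.zeros(4, dtype=np.uint64)
    )

    # -- derived views -----------------------------------------------------
    @property
    def n_fil(self) -> int:
        return self.state.shape[0]

    @property
    def n_xb(self) -> int:
        return self.state.shape[1]

    @property
    def n_motors(self) -> int:
        return self.state.size

    def attached_mask(self) -> np.ndarray:
        return self.state >= S0

    def x(self) -> np.ndarray:
        """Elastic extension of every motor (NaN for detached)."""
        out = np.full(self.state.shape, np.nan)
        m = self.attached_mask()
        out[m] = self.cc[m] + self.z
        return out

    def tension_per_filament(self) -> np.ndarray:
        """Signed elastic tension per thick filament, pN."""
        m = self.attached_mask()
        contrib = np.where(m, self.cc + self.z, 0.0)
        return self.kappa_m * contrib.sum(axis=1)

    def tension(self) -> float:
        """Ensemble-mean filament tension, pN."""
        return float(self.tension_per_filament().mean())

    def occupancy(self) -> dict[str, int]:
        counts = np.bincount(self.state.ravel(), minlength=5)
        return dict(zip(STATE_NAMES, counts.tolist()))

    def motor(self, i_fil: int, j: int) -> MotorRecord:
        s = int(self.state[i_fil, j])
        if s >= S0:
            return MotorRecord(
                state=STATE_NAMES[s],
                x=float(self.cc[i_fil, j] + self.z),
                x0=float(self.x0[i_fil, j]),
                anchor=float(self.anchors[j]),
                well=s - S0,
            )
        return MotorRecord(
            state=STATE_NAMES[s], x=None, x0=None,
            anchor=float(self.anchors[j]), well=None,
        )

    def copy(self) -> "HalfSarcomereState":
        return HalfSarcomereState(
            state=self.state.copy(), cc=self.cc.copy(), x0=self.x0.copy(),
            phi=self.phi.copy(), anchors=self.anchors.copy(),
            z=self.z, t=self.t, atp_count=self.atp_count, t0=self.t0,
            kappa_m=self.kappa_m, starved=self.starved,
            rng_state=self.rng_state.copy(),
        )


def _anchor_layout(params: ModelParameters) -> np.ndarray:
    """Strictly increasing anchor positions for ``n_xb`` heads on [LB, LM].

    The first 54 (or fewer) heads sit on the crown lattice proper; extra
    heads -- the 2-D scaling from 27 molecules per actin filament up to 76
    heads -- are interleaved at half-spacing, standing in for heads
    contributed by neighbouring thick filaments.
    """
    crowns = crown_positions(params.lm, params.lb, params.crown_spacing)
    n = params.n_xb
    if n <= crowns.size:
        return crowns[:n].copy()
    extra = params.lb + params.crown_spacing * (1.5 + np.arange(n - crowns.size))
    if extra.size and extra[-1] > params.lm:
        raise ParameterError(
            f"cannot place {n} heads on [{params.lb}, {params.lm}] "
            f"with spacing {params.crown_spacing}"
        )
    return np.sort(np.concatenate([crowns, extra]))


def build_lattice(
    params: ModelParameters, seed: int | None = None
) -> HalfSarcomereState:
    """Build the initial half-sarcomere state: all motors OFF, z = 0.

    The candidate-site phases ``phi`` are drawn once per motor from the seed
    (default ``params.seed``); rebuilding with the same seed is bit-identical.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    anchors = _anchor_layout(params)
    shape = (params.n_fil, params.n_xb)
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, params.site_period, size=shape)
    return HalfSarcomereState(
        state=np.full(shape, OFF, dtype=np.int8),
        cc=np.full(shape, np.nan),
        x0=np.full(shape, np.nan),
        phi=phi,
        anchors=anchors,
        z=0.0,
        t=0.0,
        atp_count=0,
        t0=params.t0,
        kappa_m=params.kappa_m,
    )
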