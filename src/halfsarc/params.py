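"""Model parameters for the half-sarcomere simulator.

A single :class:`ModelParameters` record carries every physical and kinetic
constant of both model wirings:

* ``conventional`` -- detached/weakly-attached two-state gate with
  nearest-neighbour cooperativity ``gamma**n`` on the thin filament;
* ``ms`` -- mechanosensing wiring, in which the OFF->ON rate of detached
  motors is multiplied by ``ON_f(T) = m + (1-m) exp(-t_f / T_rel**2)``,
  a function of the tension borne by the thick filament.

Units are nm, pN, pN nm and seconds throughout unless a field name says
otherwise.  ``KT`` is fixed so that one ATP (85 pN nm) is exactly 20 KT,
keeping the energy bookkeeping of the landscape (8 KT drop per power-stroke
step, 5.8 KT sinusoidal barrier) self-consistent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "load_params",
    "save_params",
    "reference_params",
]

OFF, ON, S0, S1, S2 = 0, 1, 2, 3, 4
STATE_NAMES = ("OFF", "ON", "S0", "S1", "S2")


class ParameterError(ValueError):
    """Raised when a parameter set violates a structural invariant."""


# Mapping of config-file sections to field names.  The config format is a
# nested YAML document; sections mirror the package modules.
_SECTIONS = {
    "model": ["model_kind", "seed"],
    "geometry": ["n_fil", "n_xb", "la", "lm", "lb", "crown_spacing"],
    "mechanics": ["kappa_m", "kappa_well", "t0"],
    "landscape": ["kt", "h_kt", "bias_kt", "d", "e_atp", "nu_attempt"],
    "attachment": [
        "f1", "g1", "g2", "x_lim", "x_dislodge", "x_jitter", "site_period",
    ],
    "on_off": ["k01_0", "k10_0", "m", "t_f", "gamma"],
    "engine": [
        "dt", "record_dt", "activation_ramp_ms", "detach_to",
        "onf_tension_mode",
    ],
}


@dataclass
class ModelParameters:
    # -- model selection ---------------------------------------------------
    model_kind: str = "ms"              # {"ms", "conventional"}
    seed: int = 0

    # -- half-sarcomere geometry ------------------------------------------
    n_fil: int = 50                     # thick/thin filament couples
    n_xb: int = 76                      # myosin heads per thick filament
    la: float = 1224.0                  # thin half-filament length, nm
    lm: float = 825.0                   # thick half-filament length, nm
    lb: float = 50.0                    # bare zone, nm
    crown_spacing: float = 14.3         # myosin crown spacing, nm

    # -- mechanics ---------------------------------------------------------
    kappa_m: float = 2.0                # motor elastic stiffness, pN/nm
    kappa_well: float = 48.0            # landscape well stiffness, pN/nm
    t0: float = 140.0                   # reference plateau tension per thick
                                        # filament, pN (set by calibration)

    # -- energy landscape --------------------------------------------------
    kt: float = 4.25                    # thermal energy, pN nm (E_ATP/20)
    h_kt: float = 5.8                   # sinusoidal barrier, units of KT
    bias_kt: float = 8.0                # ATP bias per power-stroke step, KT
    d: float = 5.5                      # inter-minimum distance, nm
    e_atp: float = 85.0                 # energy per ATP, pN nm
    nu_attempt: float = 4.0e4           # well-hopping attempt frequency, 1/s

    # -- attachment / detachment (H57) ------------------------------------
    f1: float = 25.0                    # attach-rate slope, 1/(s nm)
    g1: float = 15.0                    # detach-rate slope for x>0, 1/(s nm)
    g2: float = 2000.0                  # detach rate for x<=0, 1/s
    x_lim: float = 7.0                  # upper strain bound for attachment, nm
    x_dislodge: float = 20.0            # forced-detachment strain, nm
    x_jitter: float = 2.5               # attachment jitter half-width, nm
    site_period: float = 11.0           # candidate-site periodicity, nm

    # -- OFF/ON gate -------------------------------------------------------
    k01_0: float = 200.0                # baseline OFF->ON rate, 1/s
    k10_0: float = 38.0                 # ON->OFF rate, 1/s
    m: float = 0.01                     # low-tension floor of ON_f
    t_f: float = 0.06                   # ON_f tension scale, (T/T0)^2 units
    gamma: float = 1.0                  # cooperativity factor (conventional)

    # -- engine ------------------------------------------------------------
    dt: float = 2.0e-6                  # Monte-Carlo time step, s
    record_dt: float = 2.0e-4           # trace sampling interval, s
    activation_ramp_ms: float = 1.0     # thin-filament activation ramp, ms
    detach_to: str = "auto"             # {"auto", "on", "off"}
    onf_tension_mode: str = "per_filament"  # or "ensemble"

    # ---------------------------------------------------------------------
    @property
    def f_atp(self) -> float:
        """Tilt force of the landscape, pN (= bias_kt*KT / d)."""
        return self.bias_kt * self.kt / self.d

    @property
    def h(self) -> float:
        """Sinusoidal barrier height, pN nm."""
        return self.h_kt * self.kt

    @property
    def n_motors(self) -> int:
        return self.n_fil * self.n_xb

    @property
    def detach_dest(self) -> int:
        """Destination state index of a detachment event."""
        if self.detach_to == "on":
            return ON
        if self.detach_to == "off":
            return OFF
        return ON if self.model_kind == "ms" else OFF

    # ---------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self
        def req(cond: bool, msg: str) -> None:
            if not cond:
                raise ParameterError(msg)

        req(p.model_kind in ("ms", "conventional"),
            f"unknown model_kind {p.model_kind!r}")
        req(p.detach_to in ("auto", "on", "off"),
            f"unknown detach_to {p.detach_to!r}")
        req(p.onf_tension_mode in ("per_filament", "ensemble"),
            f"unknown onf_tension_mode {p.onf_tension_mode!r}")
        req(p.n_fil >= 1 and p.n_xb >= 0, "n_fil >= 1 and n_xb >= 0 required")
        req(p.lm > p.lb >= 0, "LM > LB >= 0 required")
        req(p.la > 0, "LA > 0 required")
        req(p.crown_spacing > 0, "crown_spacing > 0 required")
        for name in ("kappa_m", "kappa_well", "kt", "h_kt", "d", "dt",
                     "nu_attempt", "g2", "t0", "e_atp", "site_period",
                     "record_dt"):
            req(getattr(p, name) > 0, f"{name} must be strictly positive")
        for name in ("f1", "g1", "k01_0", "k10_0"):
            req(getattr(p, name) >= 0, f"{name} must be non-negative")
        req(0 < p.m < 1, "0 < m < 1 required")
        # t_f == 0 is the documented sentinel disabling mechanosensing
        # (ON_f identically 1); otherwise strictly positive.
        req(p.t_f >= 0, "t_f >= 0 required")
        req(p.gamma >= 1, "gamma >= 1 required")
        req(p.x_dislodge > p.x_lim > 0, "x_dislodge > x_lim > 0 required")
        req(p.x_lim < p.site_period, "x_lim must be below site_period")
        req(p.x_jitter >= 0, "x_jitter >= 0 required")
        # The bias per landscape step is exactly bias_kt*KT by construction
        # (f_atp is derived); guard against absurd overrides elsewhere.
        req(abs(p.f_atp * p.d - p.bias_kt * p.kt) < 1e-9,
            "F_atp * d must equal bias_kt * KT")

    # -- config round-trip -------------------------------------------------
    def to_config(self) -> dict[str, dict[str, Any]]:
        return {
            sec: {name: getattr(self, name) for name in names}
            for sec, names in _SECTIONS.items()
        }

    @classmethod
    def from_config(cls, cfg: dict[str, Any]) -> "ModelParameters":
        flat: dict[str, Any] = {}
        for sec, entries in cfg.items():
            if not isinstance(entries, dict):
                raise ParameterError(f"config section {sec!r} is not a mapping")
            for name, value in entries.items():
                if not any(name in names for names in _SECTIONS.values()):
                    raise ParameterError(f"unknown parameter {sec}.{name}")
                flat[name] = value
        return cls(**flat)

    def replace(self, **kw: Any) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    def digest(self) -> str:
        """Stable hash of the parameter set, for run manifests."""
        blob = json.dumps(self.to_config(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_params(path: str | Path) -> ModelParameters:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        raise ParameterError(f"empty config file: {path}")
    return ModelParameters.from_config(cfg)


def save_params(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_config(), fh, sort_keys=False)


def reference_params(model_kind: str = "ms") -> ModelParameters:
    """Load the frozen reference parameter set shipped with the package.

    These are the calibration module's output under the stated constraints
    (resting ON fraction ~5%, ~1/3 attached at the tetanus plateau, rise
    time constant ~34 ms, unloaded velocity comparable to frog fibres at
    4 C), one file per model wiring.
    """
    name = {"ms": "params_ms.yaml", "conventional": "params_conventional.yaml"}
    try:
        ref = resources.files("halfsarc.data").joinpath(name[model_kind])
    except KeyError:
        raise ParameterError(f"unknown model_kind {model_kind!r}") from None
    with resources.as_file(ref) as path:
        return load_params(path)


def boltzmann(energy: float, kt: float) -> float:
    """exp(-energy/KT), the factor behind every detailed-balance check."""
    return math.exp(-energy / kt)
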