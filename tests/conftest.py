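"""Session-scoped simulation bundles shared across the test suite.

The expensive Monte-Carlo runs (tetanus-plateau preparations, recovery
protocols, load-clamp sweeps) are computed once per session and reused by
every test that asserts on them.
"""

from __future__ import annotations

import numpy as np
import pytest

from halfsarc.analysis import energetics
from halfsarc.params import ModelParameters, reference_params
from halfsarc.protocols import (
    isometric_activation, load_clamp_fv, prepare_plateau,
    release_restretch, run,
)

from _utils import atp_rate_tail, clamp_velocity, fit_recovery_tau, fit_rise


@pytest.fixture(scope="session")
def ms_ref() -> ModelParameters:
    return reference_params("ms")


@pytest.fixture(scope="session")
def conv_ref() -> ModelParameters:
    return reference_params("conventional")


def _transient_bundle(params, seeds):
    """Per seed: activation rise + 20/40 ms zero-load recovery fits."""
    out = {"tau_r": [], "delay": [], "tau20": [], "tau40": [],
           "plateau": [], "attached": [], "atp": [], "activations": []}
    for seed in seeds:
        tr, state = run(isometric_activation(400.0), params, seed)
        fit, plat = fit_rise(tr)
        out["tau_r"].append(fit.tau_ms)
        out["delay"].append(fit.delay_ms)
        out["plateau"].append(plat)
        att = (tr.n_s0 + tr.n_s1 + tr.n_s2)[-tr.t.size // 4:].mean()
        out["attached"].append(att / params.n_motors)
        out["atp"].append(atp_rate_tail(tr))
        out["activations"].append(tr)
        for t_ms, key in ((20.0, "tau20"), (40.0, "tau40")):
            tr2, _ = run(release_restretch(t_ms, recovery_ms=300.0), params,
                         seed * 7 + int(t_ms), initial_state=state)
            out[key].append(fit_recovery_tau(tr2, t_ms * 1e-3).tau_ms)
    return out


@pytest.fixture(scope="session")
def ms_transients(ms_ref):
    """Eight-seed MS transient set at the reference size (N_fil = 50)."""
    return _transient_bundle(ms_ref, seeds=(21, 22, 23, 24, 25, 26, 27, 28))


@pytest.fixture(scope="session")
def conv_transients(conv_ref):
    """Three-seed conventional transient set at N_fil = 50."""
    return _transient_bundle(conv_ref, seeds=(21, 22, 23))


def _fv_sweep(params, seed=3, loads=(0.0, 0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.75)):
    p = params.replace(n_fil=16)
    state = prepare_plateau(p, seed)
    rows = []
    for load, proto in zip(loads, load_clamp_fv(loads, duration_ms=150.0)):
        tr, _ = run(proto, p, seed + int(load * 100), initial_state=state)
        e = energetics(tr, window=(0.03, float(tr.t[-1])))
        rows.append({
            "load": load, "velocity": clamp_velocity(tr),
            "atp_rate": e.atp_rate, "efficiency": e.efficiency,
        })
    return rows


@pytest.fixture(scope="session")
def ms_fv(ms_ref):
    return _fv_sweep(ms_ref)


@pytest.fixture(scope="session")
def conv_fv(conv_ref):
    return _fv_sweep(conv_ref)
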