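"""Monte-Carlo engine mechanics: force balance, sampling, conservation,
reproducibility and boundary conditions."""

import numpy as np
import pytest

from halfsarc.engine import (
    BoundaryCondition, EngineError, Segment, Trace, run_segments,
    solve_z_for_load, step, validate_dt,
)
from halfsarc.fixtures import make_micro_ensemble
from halfsarc.geometry import build_lattice
from halfsarc.params import ModelParameters
from halfsarc.protocols import Protocol, isometric_activation, run

P = ModelParameters()


# ----------------------------------------------------------------------
# force balance on the rigid filament system
# ----------------------------------------------------------------------

def test_single_motor_tension_hand_value():
    """One attached motor at x = 3 nm with kappa_m = 2 bears 6 pN."""
    st = make_micro_ensemble(P, ["S0"], [3.0])
    assert st.tension() == pytest.approx(6.0)


def test_empty_ensemble_bears_no_tension():
    st = make_micro_ensemble(P, ["OFF", "ON"])
    assert st.tension() == 0.0


def test_opposite_strains_cancel():
    st = make_micro_ensemble(P, ["S0", "S0"], [2.0, -2.0])
    assert st.tension() == pytest.approx(0.0)


def test_solve_z_single_motor_zero_load():
    st = make_micro_ensemble(P, ["S0"], [3.0])
    z = solve_z_for_load(st, 0.0)
    st.z = z
    assert st.tension() == pytest.approx(0.0)
    assert st.x()[0, 0] == pytest.approx(0.0)


def test_solve_z_balanced_pair_unchanged():
    st = make_micro_ensemble(P, ["S0", "S0"], [2.0, -2.0])
    assert solve_z_for_load(st, 0.0) == pytest.approx(st.z)


def test_solve_z_linear_algebra_oracle():
    """z from the closed form equals the brute-force root of the balance."""
    strains = [1.0, -2.5, 4.0, 0.5, 3.0]
    st = make_micro_ensemble(P, ["S0"] * 5, strains)
    target = 7.0     # pN per (single) filament
    z = solve_z_for_load(st, target)
    st.z = z
    assert st.tension() == pytest.approx(target)
    # brute force: scan tension(z) for the root
    zs = np.linspace(z - 5, z + 5, 200001)
    tension = P.kappa_m * (np.sum(st.cc[0, :5]) + 5 * zs)
    z_brute = zs[np.argmin(np.abs(tension - target))]
    assert z == pytest.approx(z_brute, abs=1e-4)


def test_starvation_flag_under_load_without_motors():
    st = make_micro_ensemble(P, ["ON", "OFF"])
    z0 = st.z
    z = solve_z_for_load(st, 5.0)
    assert z == z0
    assert st.starved


# ----------------------------------------------------------------------
# sampling and bookkeeping
# ----------------------------------------------------------------------

def test_no_hazards_leaves_state_untouched_except_clock():
    p = P.replace(k01_0=0.0, f1=0.0, n_fil=1, n_xb=4)
    st = build_lattice(p, seed=0)
    before = st.state.copy()
    step(st, BoundaryCondition.isometric(0.0), p)
    assert np.array_equal(st.state, before)
    assert st.t == pytest.approx(p.dt)
    assert st.atp_count == 0


def test_single_channel_transition_probability():
    """ON->OFF sampling matches 1 - exp(-k dt) (binomial check, 4000 motors)."""
    k10 = 5000.0     # k dt = 0.01
    p = P.replace(model_kind="ms", k01_0=0.0, f1=0.0, k10_0=k10, t_f=0.0,
                  n_fil=60, n_xb=60)
    st = build_lattice(p, seed=5)
    st.state[:] = 1          # every motor ON, only the OFF channel open
    n = st.n_motors
    step(st, BoundaryCondition.isometric(0.0), p)
    n_off = int((st.state == 0).sum())
    p_exact = -np.expm1(-k10 * p.dt)
    mean, sd = n * p_exact, np.sqrt(n * p_exact * (1 - p_exact))
    assert abs(n_off - mean) < 4.5 * sd


def test_dislodged_motor_detaches_same_step_and_pays_atp():
    p = P.replace(k01_0=0.0, f1=0.0, g1=0.0, g2=1e-9)
    st = make_micro_ensemble(p, ["S1"], [19.5])
    step(st, Segment(p.dt * 1e3, "length", dz=1.0), p)   # stretch past 20 nm
    assert st.occupancy()["S1"] == 0
    assert st.atp_count == 1


def test_atp_counter_equals_detachment_events():
    """Forced detachment of every attached motor costs exactly one ATP each."""
    p = P.replace(k01_0=0.0, k10_0=0.0, f1=0.0, g1=0.0, g2=50000.0, dt=1e-6)
    st = make_micro_ensemble(p, ["S0", "S1", "S2", "OFF", "ON"],
                             [-1.0, -2.0, -0.5, None, None])
    tr = run_segments(st, [Segment(2.0, "length")], p, seed=9)
    assert st.atp_count == 3
    assert int(tr.atp[-1]) == 3
    assert np.all(np.diff(tr.atp) >= 0)


def test_occupancy_conserved_through_rich_protocol(ms_ref):
    p = ms_ref.replace(n_fil=4)
    proto = Protocol(id="mix", segments=(
        Segment(20.0, "length"),
        Segment(10.0, "length", dz=-4.0),
        Segment(20.0, "load", load_rel=0.3),
        Segment(10.0, "length"),
    ), initial_condition="tetanus_plateau")
    tr, st = run(proto, p, seed=4, plateau_prep_ms=150.0)
    total = tr.n_off + tr.n_on + tr.n_s0 + tr.n_s1 + tr.n_s2
    assert np.all(total == p.n_motors)


def test_same_seed_bit_identical_traces(ms_ref):
    p = ms_ref.replace(n_fil=2)
    proto = isometric_activation(30.0)
    tr1, _ = run(proto, p, seed=12)
    tr2, _ = run(proto, p, seed=12)
    for name in ("tension", "z", "n_off", "n_on", "n_s0", "n_s1", "n_s2",
                 "atp"):
        assert np.array_equal(getattr(tr1, name), getattr(tr2, name))
    tr3, _ = run(proto, p, seed=13)
    assert not np.array_equal(tr1.tension, tr3.tension)


def test_ms_and_conventional_identical_when_feedbacks_off(ms_ref):
    """With ON_f forced to 1 and gamma = 1 the two wirings share one code
    path and produce bit-identical traces from the same seed (detachment
    destination aligned)."""
    base = dict(n_fil=2, t_f=0.0, gamma=1.0, detach_to="on",
                k01_0=100.0, k10_0=50.0, m=0.5)
    ms = ms_ref.replace(model_kind="ms", **base)
    conv = ms_ref.replace(model_kind="conventional", **base)
    proto = Protocol(id="mix", segments=(
        Segment(15.0, "length"),
        Segment(5.0, "length", dz=-3.0),
        Segment(15.0, "load", load_rel=0.2),
    ), initial_condition="all_OFF")
    tr_ms, _ = run(proto, ms, seed=7)
    tr_cv, _ = run(proto, conv, seed=7)
    for name in ("tension", "z", "n_off", "n_on", "n_s0", "n_s1", "n_s2",
                 "atp"):
        assert np.array_equal(getattr(tr_ms, name), getattr(tr_cv, name))


def test_load_clamp_holds_target_tension(ms_ref):
    p = ms_ref.replace(n_fil=8)
    proto = Protocol(id="clamp", segments=(
        Segment(60.0, "load", load_rel=0.6),),
        initial_condition="tetanus_plateau")
    tr, _ = run(proto, p, seed=6, plateau_prep_ms=250.0)
    steady = tr.tension_rel[tr.t.size // 3:]
    assert steady.mean() == pytest.approx(0.6, abs=0.02)


def test_attached_strain_bounded_by_dislodge(ms_ref):
    p = ms_ref.replace(n_fil=2)
    _, st = run(isometric_activation(50.0), p, seed=3)
    x = st.x()
    assert np.nanmax(np.abs(x)) <= p.x_dislodge


def test_dt_validation_rejects_coarse_step():
    with pytest.raises(EngineError):
        validate_dt(P.replace(dt=1e-3))


def test_trace_csv_round_trip(tmp_path, ms_ref):
    p = ms_ref.replace(n_fil=1)
    tr, _ = run(isometric_activation(10.0), p, seed=2)
    path = tmp_path / "trace.csv"
    tr.to_csv(path)
    back = Trace.from_csv(path)
    assert np.allclose(back.t, tr.t)
    assert np.allclose(back.tension, tr.tension)
    assert np.array_equal(back.atp, tr.atp)
    assert back.meta["t0"] == tr.meta["t0"]
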