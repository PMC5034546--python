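"""Trace post-processing: delayed-exponential fits, force-velocity,
energetics bookkeeping."""

import numpy as np
import pytest

from halfsarc.analysis import (
    energetics, fit_exp_with_delay, force_velocity, grid_search_fit,
    non_off_fraction,
)
from halfsarc.engine import Trace
from halfsarc.fixtures import make_exp_trace
from halfsarc.params import ParameterError


def _flat_trace(t, tension, z, n_motors=10, n_fil=1, atp=None):
    n = t.size
    zeros = np.zeros(n, dtype=np.int64)
    return Trace(
        t=t, tension=tension, z=z,
        n_off=zeros, n_on=zeros, n_s0=zeros, n_s1=zeros, n_s2=zeros,
        atp=np.zeros(n, dtype=np.int64) if atp is None else atp,
        meta={"t0": 1.0, "n_fil": n_fil, "n_motors": n_motors, "e_atp": 85.0},
    )


class TestDelayedExponentialFit:
    def test_recovers_noiseless_ground_truth(self):
        tr = make_exp_trace(30.0, 5.0, 1.0)
        fit = fit_exp_with_delay(tr)
        assert fit.tau_ms == pytest.approx(30.0, abs=0.05)
        assert fit.delay_ms == pytest.approx(5.0, abs=0.05)
        assert fit.plateau == pytest.approx(1.0, abs=1e-3)

    def test_optimiser_never_worse_than_grid_oracle(self):
        tr = make_exp_trace(24.0, 2.0, 1.0, noise_sd=0.04, seed=3)
        fit = fit_exp_with_delay(tr)
        t_ms = (tr.t - tr.t[0]) * 1e3
        _, _, _, rss_grid = grid_search_fit(t_ms, tr.tension_rel)
        assert fit.rss <= rss_grid + 1e-9

    def test_scale_equivariance(self):
        a = make_exp_trace(30.0, 5.0, 1.0, noise_sd=0.02, seed=1)
        b = _flat_trace(a.t, 5.0 * a.tension, a.z)
        fa = fit_exp_with_delay(a)
        fb = fit_exp_with_delay(b, normalize=False)
        assert fb.plateau == pytest.approx(5.0 * fa.plateau, rel=1e-3)
        assert fb.tau_ms == pytest.approx(fa.tau_ms, rel=1e-3)
        assert fb.delay_ms == pytest.approx(fa.delay_ms, abs=0.05)

    def test_fixed_plateau_mode(self):
        tr = make_exp_trace(30.0, 5.0, 1.0, noise_sd=0.02, seed=2)
        fit = fit_exp_with_delay(tr, plateau_fixed=1.0)
        assert fit.plateau == 1.0
        assert fit.tau_ms == pytest.approx(30.0, rel=0.1)

    def test_window_too_short_rejected(self):
        tr = make_exp_trace(30.0, 5.0, 1.0)
        with pytest.raises(ParameterError):
            fit_exp_with_delay(tr, window=(0.0, 1e-4))


class TestForceVelocity:
    def _clamp_trace(self, v_nm_per_ms, duration_s=0.1):
        t = np.linspace(0.0, duration_s, 200)
        z = -v_nm_per_ms * 1e3 * t
        return _flat_trace(t, np.full(t.size, 0.5), z)

    def test_velocity_and_power_identity(self):
        points, v0, pmax = force_velocity([
            (0.0, self._clamp_trace(3.0)),
            (0.5, self._clamp_trace(1.0)),
        ])
        assert v0 == pytest.approx(3.0, rel=1e-6)
        for p in points:
            assert p.power == p.load_rel * p.velocity
        assert points[0].power == 0.0
        assert pmax.load_rel == 0.5

    def test_short_trace_flagged(self):
        t = np.linspace(0.0, 0.001, 5)
        tr = _flat_trace(t, np.zeros(5), np.zeros(5))
        points, _, _ = force_velocity([(0.2, tr), (0.4, self._clamp_trace(1.0))])
        assert points[0].flagged and np.isnan(points[0].velocity)


class TestEnergetics:
    def test_hand_counted_atp_rate(self):
        """3 detachments among 10 motors over 0.1 s -> 3 ATP/myosin/s."""
        t = np.linspace(0.0, 0.1, 51)
        atp = np.minimum(3, (t * 60).astype(np.int64))
        tr = _flat_trace(t, np.ones(51), np.zeros(51), n_motors=10, atp=atp)
        res = energetics(tr)
        assert res.atp_rate == pytest.approx(3.0 / (10 * 0.1))

    def test_isometric_window_zero_efficiency(self):
        t = np.linspace(0.0, 0.1, 51)
        atp = (t * 100).astype(np.int64)
        tr = _flat_trace(t, np.ones(51), np.zeros(51), atp=atp)
        assert energetics(tr).efficiency == 0.0

    def test_zero_atp_events_flagged(self):
        t = np.linspace(0.0, 0.1, 51)
        tr = _flat_trace(t, np.ones(51), -10.0 * t)
        res = energetics(tr)
        assert res.flagged and np.isnan(res.efficiency)

    def test_work_changes_sign_with_direction(self):
        t = np.linspace(0.0, 0.1, 51)
        atp = (t * 100).astype(np.int64)
        shortening = energetics(_flat_trace(t, np.ones(51), -10 * t, atp=atp))
        lengthening = energetics(_flat_trace(t, np.ones(51), 10 * t, atp=atp))
        assert shortening.work > 0 > lengthening.work
        assert shortening.efficiency == pytest.approx(-lengthening.efficiency)


class TestNonOffFraction:
    def test_all_off_gives_zero_all_attached_gives_one(self):
        n = 5
        zeros = np.zeros(n, dtype=np.int64)
        t = np.linspace(0, 1, n)
        tr_off = Trace(t=t, tension=np.zeros(n), z=np.zeros(n),
                       n_off=np.full(n, 10), n_on=zeros, n_s0=zeros,
                       n_s1=zeros, n_s2=zeros, atp=zeros,
                       meta={"n_motors": 10})
        assert np.all(non_off_fraction(tr_off) == 0.0)
        tr_att = Trace(t=t, tension=np.zeros(n), z=np.zeros(n),
                       n_off=zeros, n_on=zeros, n_s0=np.full(n, 4),
                       n_s1=np.full(n, 3), n_s2=np.full(n, 3), atp=zeros,
                       meta={"n_motors": 10})
        assert np.all(non_off_fraction(tr_att) == 1.0)
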