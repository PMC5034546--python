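"""Rate-function laws: mechanosensing factor, cooperativity, H57 hazards."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halfsarc.kinetics import (
    RateContext, attach_rate, check_dislodge, detach_rate, off_on_rates,
    on_factor,
)
from halfsarc.params import ModelParameters, ParameterError

P = ModelParameters()


class TestOnFactor:
    def test_zero_tension_limit_is_floor(self):
        assert on_factor(0.0, 0.02, 0.05) == pytest.approx(0.02)

    def test_high_tension_limit_is_one(self):
        assert on_factor(1e6, 0.02, 0.05) == pytest.approx(1.0, abs=1e-9)

    def test_characteristic_tension_value(self):
        m, tf = 0.02, 0.05
        t = np.sqrt(tf)
        assert on_factor(t, m, tf) == pytest.approx(m + (1 - m) * np.exp(-1))

    def test_negative_tension_clamped(self):
        assert on_factor(-0.3, 0.02, 0.05) == pytest.approx(0.02)

    def test_sentinel_tf_zero_disables_mechanosensing(self):
        assert on_factor(0.0, 0.02, 0.0) == 1.0
        assert on_factor(0.7, 0.02, 0.0) == 1.0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(t=st.floats(1e-4, 10.0), dt=st.floats(1e-4, 1.0))
    def test_monotone_increasing_and_bounded(self, t, dt):
        m, tf = 0.02, 0.05
        lo, hi = on_factor(t, m, tf), on_factor(t + dt, m, tf)
        assert m <= lo <= hi < 1.0

    def test_invalid_floor_rejected(self):
        with pytest.raises(ParameterError):
            on_factor(0.5, 1.5, 0.05)


class TestOffOnGate:
    def test_conventional_no_neighbours(self):
        ctx = RateContext(n_neighbors=0, model_kind="conventional")
        assert off_on_rates(ctx, P) == (P.k01_0, P.k10_0)

    def test_conventional_two_neighbours_boost(self):
        p = P.replace(gamma=3.0)
        ctx = RateContext(n_neighbors=2, model_kind="conventional")
        k01, k10 = off_on_rates(ctx, p)
        assert k01 == pytest.approx(p.k01_0 * 9.0)
        assert k10 == pytest.approx(p.k10_0 / 9.0)

    def test_ms_zero_tension_floor(self):
        ctx = RateContext(t_rel=0.0, model_kind="ms")
        k01, k10 = off_on_rates(ctx, P)
        assert k01 == pytest.approx(P.m * P.k01_0)
        assert k10 == P.k10_0

    def test_unknown_wiring_rejected(self):
        with pytest.raises(ParameterError):
            off_on_rates(RateContext(model_kind="other"), P)

    def test_invalid_neighbour_count(self):
        with pytest.raises(ParameterError):
            RateContext(n_neighbors=3)


class TestH57:
    def test_attach_zero_for_compressed_motor(self):
        assert attach_rate(-1.0, P) == 0.0

    def test_attach_linear_in_window(self):
        assert attach_rate(P.x_lim, P) == pytest.approx(
            2.0 * attach_rate(P.x_lim / 2, P))

    def test_attach_zero_beyond_limit(self):
        assert attach_rate(P.x_lim + 1e-9, P) == 0.0

    def test_detach_linear_positive_strain(self):
        assert detach_rate(2.0, P) == pytest.approx(2.0 * P.g1)

    def test_detach_fast_constant_negative_strain(self):
        assert detach_rate(-0.5, P) == P.g2
        assert detach_rate(-5.0, P) == P.g2

    def test_detach_boundary_on_fast_branch(self):
        assert detach_rate(0.0, P) == P.g2

    @pytest.mark.parametrize("x, expected", [
        (20.5, True), (-20.5, True), (19.9, False),
    ])
    def test_dislodge_threshold(self, x, expected):
        assert check_dislodge(x, P) is expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(x=st.floats(-25.0, 25.0))
    def test_rates_non_negative_everywhere(self, x):
        assert attach_rate(x, P) >= 0.0
        assert detach_rate(x, P) >= 0.0
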