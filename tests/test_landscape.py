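"""Three-well tilted landscape: construction, C1 smoothness, Kramers rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from halfsarc.landscape import (
    build_landscape, hop_rates, stroke_geometry, total_energy,
)
from halfsarc.params import ModelParameters, ParameterError

P = ModelParameters()
SPEC = build_landscape(3.0, P)


def test_energy_drops_eight_kt_per_step():
    e = [SPEC._energy_scalar(x) for x in SPEC.minima]
    assert e[0] - e[1] == pytest.approx(8.0 * P.kt, rel=1e-12)
    assert e[1] - e[2] == pytest.approx(8.0 * P.kt, rel=1e-12)


def test_minima_are_stationary_points():
    h = 1e-6
    for xm in SPEC.minima:
        de = (SPEC._energy_scalar(xm + h) - SPEC._energy_scalar(xm - h)) / (2 * h)
        assert abs(de) < 1e-6


def test_curvature_at_minima_is_kappa_well():
    h = 1e-4
    for xm in SPEC.minima:
        d2 = (SPEC._energy_scalar(xm + h) - 2 * SPEC._energy_scalar(xm)
              + SPEC._energy_scalar(xm - h)) / h**2
        assert d2 == pytest.approx(P.kappa_well, rel=1e-4)


def test_landscape_is_c1_on_fine_grid():
    """No derivative jump beyond what curvature alone explains."""
    x = np.linspace(SPEC.minima[2] - 1.0, SPEC.minima[0] + 1.0, 20001)
    e = SPEC.energy(x)
    de = np.diff(e) / np.diff(x)
    jumps = np.abs(np.diff(de))
    h = x[1] - x[0]
    # bound: max |E''| * h with E'' <= kappa_well everywhere
    assert jumps.max() < 1.5 * P.kappa_well * h


def test_saddles_sit_between_wells_at_derived_barrier():
    geo = stroke_geometry(P)
    assert geo.barrier_fwd == pytest.approx(7.880 * P.kt, rel=1e-3)
    for k in range(2):
        assert SPEC.minima[k + 1] < SPEC.saddles[k] < SPEC.minima[k]
        assert SPEC.saddle_energies[k] - SPEC.well_energies[k] == pytest.approx(
            geo.barrier_fwd)


def test_total_energy_examples():
    assert total_energy(0, 0.0, SPEC, P) == 0.0
    assert total_energy(1, 0.0, SPEC, P) == pytest.approx(-8.0 * P.kt)
    with pytest.raises(ParameterError):
        total_energy(3, 0.0, SPEC, P)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(x=st.floats(-8.0, 8.0), well=st.integers(0, 1))
def test_detailed_balance_forward_backward(x, well):
    """r_fwd/r_bwd equals the Boltzmann factor of the total-energy change.

    A forward stroke takes the motor from well k at extension x to well k+1
    at extension x + d.
    """
    rf, _ = hop_rates(well, x, P)
    _, rb = hop_rates(well + 1, x + P.d, P)
    if rf == 0.0 or rb == 0.0 or rf == P.nu_attempt or rb == P.nu_attempt:
        return      # capped or cut off: ratio contract does not apply
    de = (total_energy(well + 1, x + P.d, SPEC, P)
          - total_energy(well, x, SPEC, P))
    assert rf / rb == pytest.approx(np.exp(-de / P.kt), rel=1e-9)


def test_zero_stiffness_ratio_is_e_to_the_eight():
    """With no elastic penalty the bias per step fixes the rate ratio at e^8."""
    p0 = ModelParameters(kappa_m=1e-12)
    rf, _ = hop_rates(0, 1.0, p0)
    _, rb = hop_rates(1, 1.0 + p0.d, p0)
    assert rf / rb == pytest.approx(np.exp(8.0), rel=1e-6)


def test_untilted_symmetric_wells_hop_equally():
    p0 = ModelParameters(kappa_m=1e-12, bias_kt=0.0)
    rf, _ = hop_rates(0, 0.0, p0)
    _, rb = hop_rates(1, 0.0, p0)
    assert rf == pytest.approx(rb, rel=1e-9)


def test_barrierless_hop_capped_at_attempt_frequency():
    # deep negative extension removes the forward barrier entirely
    rf, _ = hop_rates(0, -30.0, P)
    assert rf == P.nu_attempt


def test_terminal_wells_have_no_outward_hops():
    rf, rb = hop_rates(0, 0.0, P)
    assert rb == 0.0
    rf2, rb2 = hop_rates(2, 0.0, P)
    assert rf2 == 0.0


def test_invalid_geometry_rejected():
    with pytest.raises(ParameterError):
        build_landscape(0.0, ModelParameters(h_kt=0.1, bias_kt=8.0))
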