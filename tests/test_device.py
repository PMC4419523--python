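"""Synapse device model: reads, threshold gating, saturating updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memhnn.device import (
    DeviceParams,
    SynapseState,
    apply_pulse,
    calibrate_rate,
    pulse_train,
    read_current,
    update_conductance,
)

P = DeviceParams()


class TestReadCurrent:
    @pytest.mark.parametrize(
        "g, v, expected",
        [
            (3.5, 1.0, 3.5),  # conductance at unit read voltage
            (2.2, 0.0, 0.0),  # zero bias
            (1.5, 1.0, 1.5),  # minimum-conductance device at the read voltage
        ],
    )
    def test_linear_read(self, g, v, expected):
        assert read_current(SynapseState(g), v, P) == pytest.approx(expected)

    def test_read_outside_regime_rejected(self):
        with pytest.raises(ValueError):
            read_current(SynapseState(3.5), 1.5, P)


class TestApplyPulse:
    def test_rate_window_at_gmin(self):
        dg = apply_pulse(SynapseState(P.g_min), P, 2.0).g - P.g_min
        assert 0.2 <= dg <= 0.5

    def test_rate_window_near_saturation(self):
        g0 = P.g_max - 0.1 * P.g_range  # 10% headroom left
        dg = apply_pulse(SynapseState(g0), P, 2.0).g - g0
        assert 0.02 <= dg <= 0.05

    def test_subthreshold_pulse_is_inert(self):
        s = SynapseState(3.5)
        for v in (1.0, -1.0, 0.5, 0.0):
            assert apply_pulse(s, P, v).g == 3.5

    def test_saturation_fixed_points(self):
        assert apply_pulse(SynapseState(P.g_max), P, 2.0).g == P.g_max
        assert apply_pulse(SynapseState(P.g_min), P, -2.0).g == P.g_min

    def test_depression_mirrors_potentiation(self):
        up = apply_pulse(SynapseState(P.g_min), P, 2.0).g - P.g_min
        down = P.g_max - apply_pulse(SynapseState(P.g_max), P, -2.0).g
        assert up == pytest.approx(down)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            apply_pulse(SynapseState(3.5), P, float("nan"))

    def test_disturb_model_scales_update(self):
        pd = DeviceParams(disturb_enabled=True, disturb_fraction=0.1)
        full = apply_pulse(SynapseState(3.0), pd, 2.0).g - 3.0
        disturb = apply_pulse(SynapseState(3.0), pd, 1.0).g - 3.0
        assert disturb == pytest.approx(0.1 * full)

    def test_jitter_is_seeded_and_inside_window(self):
        pj = DeviceParams(jitter=True)
        rates = [
            apply_pulse(SynapseState(P.g_min), pj, 2.0, np.random.default_rng(k)).g
            - P.g_min
            for k in range(20)
        ]
        assert all(0.2 <= r <= 0.5 for r in rates)
        again = (
            apply_pulse(SynapseState(P.g_min), pj, 2.0, np.random.default_rng(0)).g
            - P.g_min
        )
        assert again == rates[0]


class TestCalibrateRate:
    @pytest.mark.parametrize("target, alpha", [(0.35, 0.0875), (0.2, 0.05)])
    def test_alpha_from_target(self, target, alpha):
        p = calibrate_rate(P, target)
        assert p.alpha_pot == pytest.approx(alpha)
        assert p.alpha_dep == pytest.approx(alpha)
        dg = apply_pulse(SynapseState(p.g_min), p, 2.0).g - p.g_min
        assert dg == pytest.approx(target)

    def test_target_outside_window_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate(P, 0.6)


class TestPulseTrain:
    def test_potentiation_converges_to_gmax(self):
        g = pulse_train(SynapseState(P.g_min), P, 500, "potentiate")
        assert np.all(np.diff(g) >= 0)
        assert g[-1] == pytest.approx(5.5, rel=1e-6)

    def test_depression_converges_to_gmin(self):
        g = pulse_train(SynapseState(P.g_max), P, 500, "depress")
        assert np.all(np.diff(g) <= 0)
        assert g[-1] == pytest.approx(1.5, rel=1e-6)

    def test_single_pulse_matches_apply_pulse(self):
        g = pulse_train(SynapseState(3.0), P, 1, "potentiate")
        assert g[0] == apply_pulse(SynapseState(3.0), P, 2.0).g

    def test_symmetric_responses_mirror(self):
        up = pulse_train(SynapseState(P.g_min), P, 50, "potentiate")
        down = pulse_train(SynapseState(P.g_max), P, 50, "depress")
        np.testing.assert_allclose(up - P.g_min, P.g_max - down, atol=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pulse_train(SynapseState(3.0), P, 0)
        with pytest.raises(ValueError):
            pulse_train(SynapseState(3.0), P, 5, "sideways")


@given(
    g0=st.floats(1.5, 5.5),
    pulses=st.lists(st.floats(-3.0, 3.0, allow_nan=False), min_size=1, max_size=60),
)
@settings(deadline=None, derandomize=True)
def test_conductance_stays_bounded_under_any_pulse_storm(g0, pulses):
    s = SynapseState(g0)
    for v in pulses:
        s = apply_pulse(s, P, v)
        assert P.g_min <= s.g <= P.g_max


@given(
    g0=st.floats(1.5, 5.5),
    subthreshold=st.lists(st.floats(-1.0, 1.0, allow_nan=False), min_size=1, max_size=60),
)
@settings(deadline=None, derandomize=True)
def test_subthreshold_sequences_leave_state_bit_identical(g0, subthreshold):
    s = SynapseState(g0)
    for v in subthreshold:
        s = apply_pulse(s, P, v)
    assert s.g == g0


@given(g0=st.floats(1.5, 5.5), n=st.integers(1, 100))
@settings(deadline=None, derandomize=True)
def test_geometric_convergence_closed_form(g0, n):
    g = pulse_train(SynapseState(g0), P, n, "potentiate")
    headroom = (1 - P.alpha_pot) ** n * (P.g_max - g0)
    assert P.g_max - g[-1] == pytest.approx(headroom, abs=1e-9)


@given(
    g=st.lists(st.floats(1.5, 5.5), min_size=1, max_size=30),
    v=st.floats(-3.0, 3.0, allow_nan=False),
)
@settings(deadline=None, derandomize=True)
def test_vectorised_kernel_matches_scalar_reference(g, v):
    arr = np.array(g)
    vec = update_conductance(arr, P, np.full_like(arr, v))
    scalar = np.array([apply_pulse(SynapseState(x), P, v).g for x in g])
    np.testing.assert_array_equal(np.atleast_1d(vec), scalar)
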