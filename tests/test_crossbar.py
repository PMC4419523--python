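"""Cross-point array, half-bias voltage assignment and training loop."""

import itertools

import numpy as np
import pytest

from memhnn.codes import FeatureCode
from memhnn.crossbar import (
    Crossbar,
    LearningConfig,
    apply_bias,
    assign_depression_bias,
    assign_potentiation_bias,
    init_crossbar,
    row_currents,
    train,
)
from memhnn.decision import DEFAULT_GROUPING, label_vector
from memhnn.device import DeviceParams

CFG = LearningConfig()
P = DeviceParams()


def toy_code(bits, label=None):
    return FeatureCode(bits=tuple(bits), label=label)


class TestInit:
    def test_default_array_is_192_cells_at_midpoint(self):
        xbar = init_crossbar(CFG, P)
        assert (xbar.n_rows, xbar.n_cols) == (6, 32)
        assert xbar.n_cells == 192
        assert np.all(xbar.g == 3.5)

    def test_out_of_bounds_init_rejected(self):
        with pytest.raises(ValueError):
            init_crossbar(LearningConfig(init_g=9.9), P)

    def test_line_voltage_invariants_enforced(self):
        with pytest.raises(ValueError):
            LearningConfig(v_cm=5.5).validate(P)  # |v_cm - v_l| > v_switch
        with pytest.raises(ValueError):
            LearningConfig(v_h=3.5).validate(P)  # write voltage below threshold


class TestBiasAssignment:
    def test_potentiation_voltages_match_half_bias_scheme(self):
        # 4 pre-neurons x 2 post-neurons toy
        bias = assign_potentiation_bias([1, 0], toy_code([1, 0, 1, 1]), CFG)
        np.testing.assert_array_equal(bias.te, [3.0, 4.0])
        np.testing.assert_array_equal(bias.be, [5.0, 4.0, 5.0, 5.0])
        v = bias.cell_voltages
        assert np.all(v[0, [0, 2, 3]] == 2.0)  # targeted cells see +2 V

    def test_depression_voltages(self):
        bias = assign_depression_bias([0, 1], toy_code([1, 0, 1, 1]), CFG)
        np.testing.assert_array_equal(bias.te, [4.0, 5.0])
        np.testing.assert_array_equal(bias.be, [3.0, 4.0, 3.0, 3.0])
        assert np.all(bias.cell_voltages[1, [0, 2, 3]] == -2.0)

    def test_all_zero_code_drives_nothing(self):
        bias = assign_potentiation_bias([1, 0], toy_code([0, 0, 0, 0]), CFG)
        assert np.all(np.abs(bias.cell_voltages) <= 1.0)

    def test_length_mismatch_rejected(self):
        xbar = init_crossbar(CFG, P, n_rows=2, n_cols=4)
        bias = assign_potentiation_bias([1, 0, 0], toy_code([1, 0, 1, 1]), CFG)
        with pytest.raises(ValueError):
            apply_bias(xbar, bias)

    def test_half_select_safety_exhaustive_on_toy(self):
        """No non-targeted cell ever exceeds the 1 V switching threshold."""
        for bits in itertools.product([0, 1], repeat=4):
            for desired in itertools.product([0, 1], repeat=2):
                code = toy_code(bits)
                for phase, bias in (
                    ("pot", assign_potentiation_bias(desired, code, CFG)),
                    ("dep", assign_depression_bias(desired, code, CFG)),
                ):
                    v = bias.cell_voltages
                    target = np.outer(desired, bits).astype(bool)
                    assert np.all(np.abs(v[target]) == 2.0)
                    assert np.all(np.abs(v[~target]) <= 1.0)

    def test_half_select_safety_random_at_full_size(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            bits = rng.integers(0, 2, 32)
            desired = rng.integers(0, 2, 6)
            code = toy_code(bits)
            pot = assign_potentiation_bias(desired, code, CFG).cell_voltages
            dep = assign_depression_bias(desired, code, CFG).cell_voltages
            target = np.outer(desired, bits).astype(bool)
            assert np.all(pot[target] == 2.0) and np.all(dep[target] == -2.0)
            assert np.all(np.abs(pot[~target]) <= 1.0)
            assert np.all(np.abs(dep[~target]) <= 1.0)

    def test_phase_antisymmetry_on_targets(self):
        code = toy_code([1, 0, 1, 1])
        pot = assign_potentiation_bias([1, 0], code, CFG).cell_voltages
        dep = assign_depression_bias([1, 0], code, CFG).cell_voltages
        target = np.outer([1, 0], code.bits).astype(bool)
        np.testing.assert_array_equal(pot[target], -dep[target])


class TestApplyBias:
    def test_only_selected_cells_change(self):
        xbar = init_crossbar(CFG, P, n_rows=2, n_cols=4)
        bias = assign_potentiation_bias([1, 0], toy_code([1, 0, 1, 1]), CFG)
        g0 = xbar.g.copy()
        apply_bias(xbar, bias, pulses=1)
        changed = xbar.g != g0
        np.testing.assert_array_equal(
            changed, np.array([[1, 0, 1, 1], [0, 0, 0, 0]], dtype=bool)
        )
        assert np.all(xbar.g[changed] > g0[changed])

    def test_all_common_mode_is_identity(self):
        from memhnn.crossbar import BiasPattern

        xbar = init_crossbar(CFG, P)
        g0 = xbar.g.copy()
        bias = BiasPattern(te=np.full(6, 4.0), be=np.full(32, 4.0), phase="potentiation")
        apply_bias(xbar, bias, pulses=3)
        np.testing.assert_array_equal(xbar.g, g0)

    def test_half_selected_rows_bit_identical(self):
        xbar = init_crossbar(CFG, P, n_rows=2, n_cols=4)
        xbar.g[:] = [[1.7, 2.9, 4.4, 5.1], [3.3, 2.2, 5.0, 1.6]]
        g0 = xbar.g.copy()
        bias = assign_potentiation_bias([1, 0], toy_code([1, 0, 1, 1]), CFG)
        apply_bias(xbar, bias)
        np.testing.assert_array_equal(xbar.g[1], g0[1])


class TestTraining:
    def test_single_epoch_equals_phase_sequence(self):
        code = FeatureCode(bits=(1, 0, 1, 1) + (0,) * 28, label="a")
        cfg = LearningConfig(epochs=1)
        a = init_crossbar(cfg, P)
        train(a, [code], DEFAULT_GROUPING, cfg)

        b = init_crossbar(cfg, P)
        desired = label_vector("a")
        apply_bias(b, assign_potentiation_bias(desired, code, cfg))
        apply_bias(b, assign_depression_bias(1 - desired, code, cfg))
        np.testing.assert_array_equal(a.g, b.g)

    def test_unlabelled_codes_rejected(self):
        xbar = init_crossbar(CFG, P)
        with pytest.raises(ValueError):
            train(xbar, [FeatureCode(bits=(0,) * 32)], DEFAULT_GROUPING, CFG)

    def test_training_is_deterministic(self, code_data):
        codes = code_data[0]
        runs = []
        for _ in range(2):
            xbar = init_crossbar(CFG, P)
            train(xbar, codes, DEFAULT_GROUPING, LearningConfig(epochs=3))
            runs.append(xbar.g.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_winning_cells_only_grow_without_depression(self):
        code = FeatureCode(bits=(1, 1) + (0,) * 30, label="a")
        cfg = LearningConfig(epochs=5, depression_mode="rival_active")
        xbar = init_crossbar(cfg, P)
        desired = label_vector("a").astype(bool)
        before = xbar.g[desired][:, :2].copy()
        train(xbar, [code], DEFAULT_GROUPING, cfg)
        assert np.all(xbar.g[desired][:, :2] >= before)


class TestRowCurrents:
    def test_uniform_array_half_active(self):
        xbar = init_crossbar(CFG, P)
        code = toy_code([1] * 16 + [0] * 16)
        np.testing.assert_allclose(row_currents(xbar, code), 56.0)

    def test_no_active_bits_no_current(self):
        xbar = init_crossbar(CFG, P)
        assert np.all(row_currents(xbar, toy_code([0] * 32)) == 0.0)

    def test_single_bit_reads_single_cell(self):
        xbar = init_crossbar(CFG, P)
        xbar.g[2, 5] = 4.25
        code = toy_code([1 if i == 5 else 0 for i in range(32)])
        assert row_currents(xbar, code)[2] == pytest.approx(4.25)


def test_conductance_matrix_text_round_trip(tmp_path):
    xbar = init_crossbar(CFG, P)
    xbar.g[3, 7] = 2.345678901
    path = tmp_path / "g.tsv"
    xbar.write_text(path)
    back = Crossbar.read_text(path, P)
    np.testing.assert_allclose(back.g, xbar.g, atol=1e-9)
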