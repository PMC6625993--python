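"""Dispense-volume inversion and pump-program construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradpump import (
    DirectionViolation,
    ExperimentConfig,
    InfeasibleTarget,
    build_program,
    build_variant_program,
    discretize,
    make_profile,
    solve_dispense_decreasing,
    solve_dispense_increasing,
)
from gradpump.program import step_decreasing, step_increasing


class TestDispenseInversion:
    """Closed-form dv solves, checked against the forward recurrence."""

    @pytest.mark.parametrize(
        "m_prev, m_target, v_prev, removal, c_max, expected",
        [
            # single-bolus step dose: dv = 0.4*50/3.6
            (0.0, 0.4, 50.0, 0.0, 4.0, 5.5555555555555554),
            # first phase of the worked TP run: (0.008*49 + 0.004*1)/3.992
            (0.0, 0.008, 50.0, 1.0, 4.0, 0.09919839679358718),
            (0.1, 0.1, 50.0, 0.0, 4.0, 0.0),  # no change, no removal
        ],
    )
    def test_increasing_examples(self, m_prev, m_target, v_prev, removal, c_max, expected):
        dv = solve_dispense_increasing(m_prev, m_target, v_prev, removal, c_max)
        assert dv == pytest.approx(expected, rel=1e-12)
        # forward substitution reproduces the target
        realized = step_increasing(m_prev, dv, v_prev, removal, c_max)
        assert realized == pytest.approx(m_target, abs=1e-15)

    @pytest.mark.parametrize(
        "m_prev, m_target, v_prev, removal, expected",
        [
            (0.4, 0.2, 50.0, 0.0, 50.0),  # halving requires doubling the volume
            (0.4, 0.2, 50.0, 2.0, 52.0),  # plus the removal
            (0.3, 0.3, 50.0, 0.0, 0.0),
        ],
    )
    def test_decreasing_examples(self, m_prev, m_target, v_prev, removal, expected):
        dv = solve_dispense_decreasing(m_prev, m_target, v_prev, removal)
        assert dv == pytest.approx(expected, rel=1e-12)
        realized = step_decreasing(m_prev, dv, v_prev, removal)
        assert realized == pytest.approx(m_target, abs=1e-15)

    def test_error_conditions(self):
        with pytest.raises(InfeasibleTarget):
            solve_dispense_increasing(0.0, 4.0, 50.0, 0.0, 4.0)
        with pytest.raises(DirectionViolation):
            solve_dispense_increasing(0.3, 0.2, 50.0, 0.0, 4.0)
        with pytest.raises(InfeasibleTarget):
            solve_dispense_decreasing(0.4, 0.0, 50.0, 0.0)
        with pytest.raises(DirectionViolation):
            solve_dispense_decreasing(0.2, 0.3, 50.0, 0.0)

    @settings(deadline=None, max_examples=200)
    @given(
        m_prev=st.floats(0.0, 1.0),
        d=st.floats(0.0, 0.5),
        v_prev=st.floats(10.0, 200.0),
        removal_frac=st.floats(0.0, 0.5),
        c_max=st.floats(2.0, 10.0),
    )
    def test_inversion_forward_duality_increasing(self, m_prev, d, v_prev, removal_frac, c_max):
        """Forward recurrence applied to the solved dv returns the target."""
        m_target = m_prev + d
        removal = removal_frac * v_prev
        dv = solve_dispense_increasing(m_prev, m_target, v_prev, removal, c_max)
        realized = step_increasing(m_prev, dv, v_prev, removal, c_max)
        assert realized == pytest.approx(m_target, rel=1e-12, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        m_target=st.floats(0.01, 1.0),
        d=st.floats(0.0, 1.0),
        v_prev=st.floats(10.0, 200.0),
        removal=st.floats(0.0, 20.0),
    )
    def test_inversion_forward_duality_decreasing(self, m_target, d, v_prev, removal):
        m_prev = m_target + d
        dv = solve_dispense_decreasing(m_prev, m_target, v_prev, removal)
        realized = step_decreasing(m_prev, dv, v_prev, removal)
        assert realized == pytest.approx(m_target, rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        v1=st.floats(10.0, 100.0),
        dv_v=st.floats(0.0, 50.0),
        removal=st.floats(0.0, 5.0),
        d_removal=st.floats(0.0, 3.0),
    )
    def test_monotone_dose(self, v1, dv_v, removal, d_removal):
        """For a fixed target step, dv grows with flask volume and removal."""
        lo = solve_dispense_increasing(0.1, 0.15, v1, removal, 4.0)
        hi_v = solve_dispense_increasing(0.1, 0.15, v1 + dv_v, removal, 4.0)
        hi_r = solve_dispense_increasing(0.1, 0.15, v1, removal + d_removal, 4.0)
        assert hi_v >= lo - 1e-12
        assert hi_r >= lo - 1e-12


class TestBuildProgram:
    def test_ts_draw_off_and_conservation(self, ts_program):
        """Pump 2 takes 0.125 mL per 1.25-min phase; 5 mL total over 50 min."""
        np.testing.assert_allclose(ts_program.du, 0.125)
        assert ts_program.dw.sum() == 0.0
        assert ts_program.du.sum() + ts_program.dw.sum() == pytest.approx(5.0)
        assert np.all(ts_program.dv > 0)
        # volume conservation: sum dv - sum removals == V_N - V_0
        lhs = ts_program.dv.sum() - (ts_program.du.sum() + ts_program.dw.sum())
        rhs = ts_program.flask_volumes[-1] - ts_program.flask_volumes[0]
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_tp_volume_recurrence_and_quantum(self, tp_program):
        cfg_res = tp_program.config.dispense_resolution
        # every dispense is an exact multiple of the instrument quantum
        ticks = tp_program.dv / cfg_res
        np.testing.assert_allclose(ticks, np.round(ticks), atol=1e-9)
        # V_i = V_{i-1} + dv_i - (du_i + dw_i) exactly
        np.testing.assert_allclose(
            np.diff(tp_program.flask_volumes),
            tp_program.dv - tp_program.du - tp_program.dw,
            atol=1e-12,
        )
        assert tp_program.dw.sum() == pytest.approx(14.0)

    def test_rates_recomputed_from_quantized_volumes(self, tp_program):
        np.testing.assert_allclose(
            tp_program.rates, 1000.0 * tp_program.dv / tp_program.dt, rtol=1e-14
        )

    def test_constant_zero_profile_is_all_zero(self):
        config = ExperimentConfig(mode="TP", c_max=4.0, v0=50.0)
        disc = discretize(make_profile("linear", 0.0, 0.0, 10.0), 5)
        program = build_program(config, disc)
        assert np.all(program.dv == 0)
        assert np.all(program.rates == 0)
        np.testing.assert_allclose(program.flask_volumes, 50.0)

    def test_variants_collapse_without_withdrawals(self):
        """With no withdrawals all planner corrections are the same program."""
        config = ExperimentConfig(mode="TP", c_max=4.0, v0=50.0)
        disc = discretize(make_profile("linear", 0.0, 0.4, 50.0), 10)
        programs = [
            build_variant_program(config, disc, v)
            for v in ("full_correction", "volume_only", "uncorrected")
        ]
        for other in programs[1:]:
            np.testing.assert_array_equal(programs[0].dv, other.dv)

    def test_setup1_is_ts_only(self):
        config = ExperimentConfig(mode="TP", c_max=4.0, v0=50.0)
        disc = discretize(make_profile("linear", 0.0, 0.4, 50.0), 10)
        with pytest.raises(Exception, match="TS-only"):
            build_variant_program(config, disc, "setup1_equal_rate")

    def test_setup1_keeps_beaker_volume_constant(self, ts_spec, ts_disc):
        program = build_variant_program(ts_spec.experiment, ts_disc, "setup1_equal_rate")
        np.testing.assert_array_equal(program.du, program.dv)
        np.testing.assert_allclose(program.flask_volumes, 50.0)

    def test_target_at_stock_concentration_infeasible(self):
        config = ExperimentConfig(mode="TP", c_max=0.4, v0=50.0)
        disc = discretize(make_profile("linear", 0.0, 0.4, 50.0), 10)
        with pytest.raises(InfeasibleTarget):
            build_program(config, disc)


class TestConfigValidation:
    def test_tp_rejects_pump2(self):
        with pytest.raises(ValueError):
            ExperimentConfig(mode="TP", c_max=4.0, v0=50.0, pump2_rate=0.1)

    def test_ts_rejects_sampling(self):
        with pytest.raises(ValueError):
            ExperimentConfig(
                mode="TS", c_max=4.0, v0=50.0, pump2_rate=0.1, sampling=((1.0, 1.0),)
            )

    def test_sampling_times_must_increase(self):
        with pytest.raises(ValueError):
            ExperimentConfig(
                mode="TP", c_max=4.0, v0=50.0, sampling=((2.0, 1.0), (1.0, 1.0))
            )
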