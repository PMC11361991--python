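"""Compartment model: derivative algebra, integrator accuracy, invariants."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respiromech import (
    DriveSignals,
    MechanicalParameters,
    abdominal_pressure,
    compartment_derivatives,
    diaphragm_displacement,
    pleural_pressure,
    simulate,
    step_response_closed_form,
)

PARAMS = MechanicalParameters()


def make_grid(duration, fs=100.0):
    return np.arange(int(round(duration * fs)) + 1) / fs


def constant_drives(t, p_rcmus=0.0, p_dimus=0.0, p_rex=0.0):
    return DriveSignals(
        t,
        np.full_like(t, p_rcmus),
        np.full_like(t, p_dimus),
        np.full_like(t, p_rex),
    )


class TestParameters:
    def test_defaults_are_reference_values(self):
        assert (PARAMS.R_l, PARAMS.C_l, PARAMS.C_pl) == (2.0, 0.2, 0.25)
        assert (PARAMS.R_ab, PARAMS.C_ab) == (1.0, 0.4)
        assert (PARAMS.R_rc, PARAMS.C_rc) == (1.0, 0.2)
        assert PARAMS.A_di == 0.08

    @pytest.mark.parametrize("field", ["R_rc", "C_ab", "A_di"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            MechanicalParameters(**{field: 0.0})


class TestDerivatives:
    @pytest.mark.parametrize(
        "state,drive,expected",
        [
            ((0, 0, 0), (0, 0, 0), (0.0, 0.0, 0.0)),
            ((0, 0, 0), (1, 0, 0), (1.0, 0.0, 0.0)),
            # abdominal equilibrium: v_ab/C_ab equals the abdominal drive
            ((0, 0.4 * 5, 0), (0, 2, 3), (0.0, 0.0, 4.0)),
        ],
    )
    def test_examples(self, state, drive, expected):
        d = compartment_derivatives(*state, *drive, PARAMS)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_input_names_offender(self):
        with pytest.raises(ValueError, match="p_dimus"):
            compartment_derivatives(0, 0, 0, 0, np.nan, 0, PARAMS)


class TestPointwiseRelations:
    def test_displacement_examples(self):
        assert diaphragm_displacement(0.0, 0.08) == 0.0
        assert diaphragm_displacement(1.2, 0.08) == pytest.approx(1.5)

    @given(v=st.floats(-5, 5), a=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_displacement_linearity(self, v, a):
        assert diaphragm_displacement(2 * v, a) == pytest.approx(
            2 * diaphragm_displacement(v, a), abs=1e-12
        )

    def test_displacement_rejects_bad_area(self):
        with pytest.raises(ValueError):
            diaphragm_displacement(1.0, 0.0)

    def test_pleural_pressure(self):
        assert pleural_pressure(0, 0, 0.25) == 0.0
        assert pleural_pressure(0.5, 0.5, 0.25) == pytest.approx(4.0)
        assert pleural_pressure(0.1, 0.7, 0.25) == pleural_pressure(0.7, 0.1, 0.25)

    def test_abdominal_pressure(self):
        assert abdominal_pressure(0, 0) == 0.0
        assert abdominal_pressure(5, 3) == pytest.approx(8.0)
        assert abdominal_pressure(2.7, 0.0) == pytest.approx(2.7)
        with pytest.raises(ValueError):
            abdominal_pressure(np.inf, 0.0)


class TestClosedForm:
    def test_limits_and_value(self):
        assert step_response_closed_form(1, 0.4, 3, 0.0) == 0.0
        assert step_response_closed_form(1, 0.4, 3, 1e6) == pytest.approx(1.2)
        tau = 1 * 0.4
        assert step_response_closed_form(1, 0.4, 3, tau) == pytest.approx(
            1.2 * (1 - np.exp(-1))
        )

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            step_response_closed_form(0, 0.4, 3, 1.0)
        with pytest.raises(ValueError):
            step_response_closed_form(1, 0.4, 3, -1.0)


class TestSimulate:
    def test_zero_drive_stays_at_equilibrium(self):
        t = make_grid(2.0)
        traj = simulate(PARAMS, constant_drives(t))
        assert np.all(traj.V_rc == 0) and np.all(traj.V_ab == 0) and np.all(traj.V_l == 0)

    def test_matches_first_order_oracle(self):
        t = make_grid(5.0)
        traj = simulate(PARAMS, constant_drives(t, p_rcmus=2.0), dt=1e-3)
        oracle = step_response_closed_form(PARAMS.R_rc, PARAMS.C_rc, 2.0, t)
        assert np.max(np.abs(traj.V_rc - oracle)) < 1e-6

    def test_abdominal_steady_state_under_robot_pressure(self):
        tau = PARAMS.R_ab * PARAMS.C_ab
        t = make_grid(12 * tau)
        traj = simulate(PARAMS, constant_drives(t, p_rex=3.0), dt=1e-3)
        assert traj.V_ab[-1] == pytest.approx(1.2, rel=1e-3)
        assert traj.x_di[-1] == pytest.approx(1.5, rel=1e-3)

    def test_lung_steady_state_gain(self):
        t = make_grid(30.0)
        traj = simulate(PARAMS, constant_drives(t, p_rcmus=1.0, p_dimus=2.0), dt=1e-3)
        v_inf = PARAMS.C_l * (traj.V_ab[-1] + traj.V_rc[-1]) / PARAMS.C_pl
        assert traj.V_l[-1] == pytest.approx(v_inf, rel=1e-3)

    def test_superposition(self):
        rng = np.random.default_rng(0)
        t = make_grid(2.0, fs=50.0)
        a = DriveSignals(t, rng.normal(size=t.size), rng.normal(size=t.size),
                         rng.normal(size=t.size))
        b = DriveSignals(t, rng.normal(size=t.size), rng.normal(size=t.size),
                         rng.normal(size=t.size))
        ta, tb = simulate(PARAMS, a), simulate(PARAMS, b)
        tab = simulate(PARAMS, a + b)
        for name in ("V_rc", "V_ab", "V_l"):
            np.testing.assert_allclose(
                getattr(tab, name), getattr(ta, name) + getattr(tb, name),
                rtol=1e-9, atol=1e-12,
            )

    def test_grid_refinement_fourth_order(self):
        t = make_grid(3.0, fs=50.0)
        drives = constant_drives(t, p_rcmus=1.5, p_dimus=1.0)
        coarse = simulate(PARAMS, drives, dt=2e-3)
        fine = simulate(PARAMS, drives, dt=1e-3)
        for name in ("V_rc", "V_ab", "V_l"):
            assert np.max(np.abs(getattr(coarse, name) - getattr(fine, name))) < 1e-8

    def test_displacement_is_scalar_multiple_of_abdominal_volume(self):
        rng = np.random.default_rng(3)
        t = make_grid(4.0, fs=50.0)
        drives = DriveSignals(t, rng.normal(size=t.size), rng.normal(size=t.size),
                              np.zeros_like(t))
        traj = simulate(PARAMS, drives)
        np.testing.assert_allclose(
            traj.x_di, 100.0 * (traj.V_ab * 1e-3) / PARAMS.A_di, rtol=0, atol=0
        )

    def test_derived_field_invariants(self):
        t = make_grid(3.0, fs=50.0)
        drives = constant_drives(t, p_dimus=2.0, p_rex=-1.0)
        traj = simulate(PARAMS, drives)
        np.testing.assert_allclose(traj.P_pl, (traj.V_ab + traj.V_rc) / PARAMS.C_pl)
        np.testing.assert_allclose(traj.P_ab, drives.P_dimus + drives.P_rex)

    def test_rejects_bad_dt(self):
        t = make_grid(1.0, fs=100.0)
        with pytest.raises(ValueError):
            simulate(PARAMS, constant_drives(t), dt=0.0)
        with pytest.raises(ValueError):
            simulate(PARAMS, constant_drives(t), dt=0.05)  # coarser than grid


class TestDriveValidation:
    def test_mismatched_lengths(self):
        t = make_grid(1.0)
        with pytest.raises(ValueError):
            DriveSignals(t, np.zeros(t.size - 1), np.zeros_like(t), np.zeros_like(t))

    def test_nonuniform_grid(self):
        t = np.array([0.0, 0.1, 0.25, 0.3])
        z = np.zeros_like(t)
        with pytest.raises(ValueError):
            DriveSignals(t, z, z, z)

    def test_too_short(self):
        with pytest.raises(ValueError):
            DriveSignals(np.array([0.0]), np.array([0.0]), np.array([0.0]), np.array([0.0]))


class TestCsvRoundTrip:
    def test_drives_lossless(self):
        rng = np.random.default_rng(1)
        t = make_grid(1.0, fs=37.0)
        drives = DriveSignals(t, rng.normal(size=t.size), rng.normal(size=t.size),
                              rng.normal(size=t.size))
        buf = io.StringIO()
        drives.to_csv(buf)
        buf.seek(0)
        back = DriveSignals.from_csv(buf)
        for name in ("t", "P_rcmus", "P_dimus", "P_rex"):
            np.testing.assert_allclose(getattr(back, name), getattr(drives, name),
                                       rtol=1e-12, atol=0)

    def test_trajectory_lossless(self):
        t = make_grid(2.0, fs=25.0)
        traj = simulate(PARAMS, constant_drives(t, p_rcmus=1.0, p_rex=0.5))
        buf = io.StringIO()
        traj.to_csv(buf)
        buf.seek(0)
        back = type(traj).from_csv(buf)
        for name in ("t", "V_rc", "V_ab", "V_l", "P_pl", "P_ab", "x_di"):
            np.testing.assert_allclose(getattr(back, name), getattr(traj, name),
                                       rtol=1e-12, atol=1e-15)
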