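"""Compartmental engine: closed-form oracles, event semantics, conservation."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from rrtpk.core import PKParameters, RRTSettings
from rrtpk.odes import (
    EventKind,
    EventRecord,
    mass_balance_audit,
    rhs,
    solve_subject,
)

from conftest import dosing_events


def linear_matrix(params, settings):
    """Independent oracle: state matrix of the non-saturable system."""
    v = params.V_cent
    ke = (params.CL_body + params.CL_RRT) / v
    fa = params.CL_RRT * params.F_Ads / v
    fd = params.CL_RRT * (1.0 - params.F_Ads) / v
    kr, kd = params.k_ads_rev, params.k_deg
    return np.array([[-ke, 0, 0], [fa, -kr, 0], [fd, kr, -kd]])


class TestRhs:
    def test_reduces_to_two_route_elimination(self, cvvhd, pip_params):
        d = rhs([220.0, 0.0, 0.0, 0.0], pip_params, cvvhd)
        ke = (3.0 + 3.0) / 22.0
        assert d[0] == pytest.approx(-ke * 220.0)
        assert d[1] == pytest.approx(0.0)
        assert d[2] == pytest.approx(3.0 / 22.0 * 220.0)
        assert d[3] == pytest.approx(3.0)

    def test_saturated_membrane_routes_full_flux_to_effluent(self, cvvhd):
        p = PKParameters(CL_body=2.0, V_cent=14.0, CL_RRT=2.0, F_Ads=0.9,
                         Ads_max=30.0)
        d = rhs([140.0, 30.0, 0.0, 0.0], p, cvvhd)
        assert d[1] == pytest.approx(0.0)  # no free binding sites, no desorption
        assert d[2] == pytest.approx(2.0 / 14.0 * 140.0)

    def test_constant_dialysis_parameterization_loses_clearance_at_capacity(self, cvvhd):
        p = PKParameters(CL_body=2.0, V_cent=14.0, CL_RRT=2.0, F_Ads=0.9,
                         Ads_max=30.0, parameterization="constant_dialysis_clrrt")
        d = rhs([140.0, 30.0, 0.0, 0.0], p, cvvhd)
        # only the dialytic share (1 - F_Ads) of CL_RRT still drains plasma
        expected = -(2.0 * 0.1 + 2.0) / 14.0 * 140.0
        assert d[0] == pytest.approx(expected)

    def test_rrt_off_freezes_circuit_exchange(self, cvvhd, pip_params):
        d = rhs([220.0, 5.0, 3.0, 2.0], pip_params, cvvhd, rrt_active=False)
        assert d[0] == pytest.approx(-3.0 / 22.0 * 220.0)
        assert d[1] == 0.0 and d[3] == 0.0


class TestClosedFormOracles:
    def test_bolus_monoexponential(self, cvvhd, pip_params):
        """Single IV bolus without adsorption/degradation follows
        D * exp(-(CL_body + CL_RRT)/V * t)."""
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=1000.0)]
        t = np.linspace(0.1, 24.0, 40)
        ke = 6.0 / 22.0
        expected = 1000.0 * np.exp(-ke * t)
        for method in ("analytic", "numeric"):
            traj = solve_subject(ev, pip_params, cvvhd, 24.0, t, method=method,
                                 rtol=1e-11, atol=1e-12)
            assert np.max(np.abs(traj.A1 - expected) / expected) < 1e-8

    def test_degradation_cascade_matches_matrix_exponential(self, cvvhd):
        """With bag degradation the linear system solution must match an
        independently built matrix-exponential propagation."""
        p = PKParameters(CL_body=3.0, V_cent=22.0, CL_RRT=3.0, k_deg=0.03)
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=1000.0)]
        t = np.array([0.5, 2.0, 7.0, 13.0, 23.0])
        traj = solve_subject(ev, p, cvvhd, 24.0, t, method="analytic")
        m = linear_matrix(p, cvvhd)
        y0 = np.array([1000.0, 0.0, 0.0])
        for ti, row in zip(t, traj.states):
            ref = expm(m * ti) @ y0
            assert np.allclose(row[:3], ref, rtol=1e-9, atol=1e-12)

    def test_reversible_adsorption_matches_matrix_exponential_with_infusion(self, cvvhd):
        p = PKParameters(CL_body=2.0, V_cent=35.0, CL_RRT=2.0, F_Ads=0.95,
                         k_ads_rev=0.07)
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=150.0, duration=0.5)]
        t = np.array([0.25, 0.5, 1.0, 6.0, 12.0])
        traj = solve_subject(ev, p, cvvhd, 12.0, t, method="analytic")
        m = linear_matrix(p, cvvhd)
        m_aug = np.zeros((4, 4))
        m_aug[:3, :3] = m
        m_aug[0, 3] = 300.0  # infusion rate mg/h
        for ti, row in zip(t, traj.states):
            y = np.array([0.0, 0.0, 0.0, 1.0])
            if ti <= 0.5:
                y = expm(m_aug * ti) @ y
            else:
                y = expm(m_aug * 0.5) @ y
                y[:3] = expm(m * (ti - 0.5)) @ y[:3]
            assert np.allclose(row[:3], y[:3], rtol=1e-8, atol=1e-10)

    def test_analytic_and_numeric_agree_on_multidose_schedule(self, cvvhd, pip_events):
        p = PKParameters(CL_body=3.0, V_cent=22.0, CL_RRT=3.0, F_Ads=0.3,
                         k_ads_rev=0.05, k_deg=0.03)
        t = np.array([0.5, 1, 2, 4, 6, 8, 32.5, 33, 34, 36, 38, 40], dtype=float)
        ta = solve_subject(pip_events, p, cvvhd, 40.0, t, method="analytic")
        tn = solve_subject(pip_events, p, cvvhd, 40.0, t, method="numeric")
        rel = np.abs(ta.states - tn.states) / (np.abs(tn.states) + 1e-9)
        assert rel.max() < 1e-6


class TestEventSemantics:
    def test_bag_change_resets_bag_but_not_plasma(self, cvvhd, pip_params):
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=1000.0),
              EventRecord("1", 8.0, EventKind.BAG_CHANGE)]
        t = np.array([7.999, 8.0, 8.001])
        traj = solve_subject(ev, pip_params, cvvhd, 10.0, t)
        assert traj.A3[1] > 100.0  # pre-event state at the change time
        assert traj.A3[2] < 1.0 and traj.A4[2] < 0.01
        assert traj.A1[2] == pytest.approx(traj.A1[0], rel=1e-3)

    def test_filter_change_resets_membrane(self, cvvhd):
        p = PKParameters(CL_body=3.0, V_cent=22.0, CL_RRT=3.0, F_Ads=0.5,
                         k_ads_rev=0.0)
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=1000.0),
              EventRecord("1", 6.0, EventKind.FILTER_CHANGE)]
        t = np.array([5.999, 6.001])
        traj = solve_subject(ev, p, cvvhd, 8.0, t)
        assert traj.A2[0] > 10.0 and traj.A2[1] < 0.1

    def test_rrt_off_keeps_bag_constant_and_body_only_decay(self, cvvhd, pip_params):
        ev = [EventRecord("1", 0.0, EventKind.DOSE, amount=1000.0),
              EventRecord("1", 4.0, EventKind.RRT_OFF)]
        t = np.array([4.0, 6.0, 8.0])
        traj = solve_subject(ev, pip_params, cvvhd, 8.0, t)
        assert traj.A3[1] == pytest.approx(traj.A3[0], rel=1e-9)
        assert traj.A4[2] == pytest.approx(traj.A4[0], rel=1e-9)
        kb = 3.0 / 22.0
        assert traj.A1[2] == pytest.approx(traj.A1[0] * math.exp(-kb * 4.0), rel=1e-7)

    def test_event_validation(self):
        with pytest.raises(ValueError):
            EventRecord("1", -1.0, EventKind.BAG_CHANGE)
        with pytest.raises(ValueError):
            EventRecord("1", 0.0, EventKind.DOSE, amount=0.0)
        with pytest.raises(ValueError):
            EventRecord("1", 0.0, EventKind.SETTINGS_CHANGE)


class TestStructuralProperties:
    def test_parameterizations_agree_without_adsorption(self, cvvhd, pip_events):
        t = np.linspace(0.5, 40.0, 30)
        base = dict(CL_body=3.0, V_cent=22.0, CL_RRT=3.0, F_Ads=0.0)
        p1 = PKParameters(**base, parameterization="constant_total_clrrt")
        p2 = PKParameters(**base, parameterization="constant_dialysis_clrrt")
        t1 = solve_subject(pip_events, p1, cvvhd, 40.0, t, method="numeric")
        t2 = solve_subject(pip_events, p2, cvvhd, 40.0, t, method="numeric")
        assert np.allclose(t1.states, t2.states, rtol=1e-9)

    def test_parameterizations_agree_far_from_capacity(self, cvvhd, pip_events):
        t = np.linspace(0.5, 40.0, 30)
        base = dict(CL_body=3.0, V_cent=22.0, CL_RRT=3.0, F_Ads=0.4,
                    Ads_max=1e12, k_ads_rev=0.0)
        p1 = PKParameters(**base, parameterization="constant_total_clrrt")
        p2 = PKParameters(**base, parameterization="constant_dialysis_clrrt")
        t1 = solve_subject(pip_events, p1, cvvhd, 40.0, t, method="numeric",
                           rtol=1e-10, atol=1e-12)
        t2 = solve_subject(pip_events, p2, cvvhd, 40.0, t, method="numeric",
                           rtol=1e-10, atol=1e-12)
        rel = np.abs(t1.states - t2.states) / (np.abs(t2.states) + 1e-6)
        assert rel.max() < 1e-6

    def test_irreversible_binding_is_monotone_and_capacity_bounded(self, cvvhd):
        p = PKParameters(CL_body=2.0, V_cent=14.0, CL_RRT=2.0, F_Ads=0.9,
                         Ads_max=25.0, k_ads_rev=0.0)
        ev = dosing_events(amount=150.0, interval=12.0, bag_changes=(0.0, 48.0))
        t = np.linspace(0.0, 60.0, 121)
        traj = solve_subject(ev, p, cvvhd, 60.0, t, method="numeric")
        assert np.all(np.diff(traj.A2) >= -1e-9)
        assert traj.A2.max() <= 25.0 * (1 + 1e-9)

    @pytest.mark.parametrize(
        "params",
        [
            dict(CL_RRT=3.0),
            dict(CL_RRT=3.0, k_deg=0.03),
            dict(CL_RRT=3.0, F_Ads=0.95, k_ads_rev=0.07),
            dict(CL_RRT=3.0, F_Ads=0.9, Ads_max=40.0, k_ads_rev=0.02),
        ],
        ids=["plain", "degradation", "reversible", "saturable"],
    )
    def test_mass_balance_closes(self, cvvhd, pip_events, params):
        p = PKParameters(CL_body=3.0, V_cent=22.0, **params)
        report = mass_balance_audit(pip_events, p, cvvhd, 40.0)
        assert report.ok, f"worst rel err {report.max_rel_err} at t={report.worst_time}"
        assert report.max_rel_err < 1e-6
        assert report.dosed_total == pytest.approx(20000.0)
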