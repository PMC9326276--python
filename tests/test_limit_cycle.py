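"""Tests of the Poincare-section search, stability and selection."""

import math

import numpy as np
import pytest

from slipgait.dynamics import NormalizedParameters, simulate_step
from slipgait.grf_processing import GRFTrial, extract_summary
from slipgait.limit_cycle import (
    DomainError,
    FixedPoint,
    NoSolutionError,
    PoincareState,
    SearchPoint,
    SweepGrid,
    assess_stability,
    classify_pattern,
    find_fixed_points,
    initial_state_at_vlc,
    make_search_point,
    refine_fixed_point,
    return_map,
    select_solution,
    step_deviations,
    stiffness_from_step_parameter,
    touchdown_angle_from_speed,
)


class TestCouplings:
    @pytest.mark.parametrize("v_g, degrees", [(0.8, 22.3), (0.15, 12.6)])
    def test_touchdown_angle_domain_endpoints(self, v_g, degrees):
        phi = touchdown_angle_from_speed(v_g)
        assert phi < 0
        assert math.degrees(abs(phi)) == pytest.approx(degrees, abs=0.05)

    def test_touchdown_angle_midpoint(self):
        assert touchdown_angle_from_speed(0.5) == pytest.approx(-0.311)

    def test_touchdown_angle_domain_error(self):
        with pytest.raises(DomainError):
            touchdown_angle_from_speed(1.2)

    def test_stiffness_domain_upper_bound(self):
        phi = touchdown_angle_from_speed(0.15)
        k = stiffness_from_step_parameter(10.5, phi, 0.3)
        assert k == pytest.approx(317, abs=0.5)

    def test_stiffness_midrange(self):
        k = stiffness_from_step_parameter(3.5, -0.311, 0.3)
        assert k == pytest.approx(53.4, abs=0.05)

    def test_stiffness_proportional_to_step_parameter(self):
        k1 = stiffness_from_step_parameter(1.0, -0.3, 0.3)
        k2 = stiffness_from_step_parameter(2.0, -0.3, 0.3)
        assert k2 == pytest.approx(2 * k1)

    def test_stiffness_singular_at_vertical(self):
        with pytest.raises(DomainError):
            stiffness_from_step_parameter(3.5, 0.0, 0.3)


class TestInitialState:
    def test_trough_encoding(self):
        state = initial_state_at_vlc(0.6, 20.0, 0.45)
        assert state.legs[0].compression == pytest.approx(0.03)
        assert state.com_position[1] == pytest.approx(0.97)
        assert state.com_velocity == (0.45, 0.0)

    def test_zero_trough_limit(self):
        state = initial_state_at_vlc(1e-9, 20.0, 0.45)
        assert state.com_position[1] == pytest.approx(1.0)

    def test_grf_at_state_equals_trough(self):
        from slipgait.dynamics import grf_from_leg

        params = NormalizedParameters(leg_stiffness=20.0, touchdown_angle=-0.3)
        state = initial_state_at_vlc(0.6, 20.0, 0.45, params)
        fv, fap = grf_from_leg(state.legs[0], params)
        assert fv == pytest.approx(0.6)
        assert fap == pytest.approx(0.0, abs=1e-12)

    def test_overcompression_rejected(self):
        with pytest.raises(DomainError):
            initial_state_at_vlc(1.2, 1.5, 0.45)


class TestReturnMap:
    def test_fixed_point_returns_close(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        params = NormalizedParameters(
            leg_stiffness=fp.search_point.leg_stiffness,
            touchdown_angle=fp.search_point.touchdown_angle)
        zpR, traj = return_map(fp.poincare_state, params)
        assert zpR is not None
        dz = np.hypot(zpR.com_height - fp.poincare_state.com_height,
                      zpR.forward_speed - fp.poincare_state.forward_speed)
        assert dz < 1e-3
        energy = traj.energy()
        assert np.ptp(energy) / energy[0] < 1e-8

    def test_fall_has_no_return_state(self):
        params = NormalizedParameters(leg_stiffness=5.0, touchdown_angle=-0.5)
        zpR, traj = return_map(PoincareState(0.9, 0.2), params)
        assert zpR is None
        assert traj.failed


class TestFixedPointSearch:
    def test_single_point_lattice_determinism(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        grid = SweepGrid(v_g0=np.array([fp.search_point.initial_speed]),
                         f_v_min0=np.array([fp.search_point.initial_trough]),
                         p_phi_k=np.array([fp.search_point.step_parameter]))
        again = find_fixed_points("F", fp.search_point.initial_trough, grid=grid)
        assert len(again) == 1
        assert again[0].deviation == pytest.approx(fp.deviation, rel=1e-12)
        assert again[0].step_length == pytest.approx(fp.step_length, rel=1e-12)

    def test_grid_refinement_keeps_fixed_points(self, stable_fixed_points):
        """A nested 2x finer step-parameter lattice re-finds every point."""
        fp = stable_fixed_points[0]
        fine = SweepGrid(v_g0=np.array([0.45]), f_v_min0=np.array([0.6]),
                         p_phi_k=np.round(np.arange(0.25, 10.6, 0.25), 10))
        fps = find_fixed_points("F", 0.6, grid=fine, stability=False,
                                classify=False)
        ps = {round(f.search_point.step_parameter, 6) for f in fps}
        assert round(fp.search_point.step_parameter, 6) in ps

    def test_empty_result_is_legal(self):
        grid = SweepGrid(v_g0=np.array([0.8]), f_v_min0=np.array([1.2]),
                         p_phi_k=np.array([0.1]))
        assert find_fixed_points("F", 1.2, grid=grid) == []

    def test_constraint_f_spans_patterns(self):
        """A coarse constraint-F sweep finds both oscillation regimes."""
        grid = SweepGrid(v_g0=np.round(np.arange(0.2, 0.51, 0.05), 10),
                         f_v_min0=np.array([0.6]),
                         p_phi_k=np.round(np.arange(0.5, 10.6, 0.5), 10))
        fps = find_fixed_points("F", 0.6, grid=grid)
        labels = {fp.pattern_label for fp in fps}
        assert "double_hump" in labels
        assert "multi_peak" in labels


class TestStability:
    def test_stable_point_eigenvalues_below_one(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        assert max(fp.eigenvalue_magnitudes) < 1.0

    def test_finite_difference_convergence(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        params = NormalizedParameters(
            leg_stiffness=fp.search_point.leg_stiffness,
            touchdown_angle=fp.search_point.touchdown_angle)
        a = assess_stability(fp.poincare_state, params, eps=1e-4)
        b = assess_stability(fp.poincare_state, params, eps=1e-5)
        assert np.allclose(a.eigenvalue_magnitudes, b.eigenvalue_magnitudes,
                           atol=1e-2)

    def test_failed_perturbation_flags_unstable(self):
        params = NormalizedParameters(leg_stiffness=5.0, touchdown_angle=-0.5)
        res = assess_stability(PoincareState(0.9, 0.2), params)
        assert not res.stable
        assert res.note

    def test_twenty_step_drift_bounded(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        params = NormalizedParameters(
            leg_stiffness=fp.search_point.leg_stiffness,
            touchdown_angle=fp.search_point.touchdown_angle)
        devs = step_deviations(fp.poincare_state, params, 20)
        assert len(devs) == 20
        assert max(devs) < 1e-2


class TestPatternClassification:
    def test_unimodal_curve_is_other(self):
        u = np.linspace(0, 1, 400)
        assert classify_pattern(np.sin(np.pi * u)) == "other"

    def test_double_hump_curve(self):
        u = np.linspace(0, 1, 400)
        fv = np.sin(np.pi * u) + 0.5 * np.sin(3 * np.pi * u)
        assert classify_pattern(fv) == "double_hump"

    def test_multi_peak_curve(self):
        u = np.linspace(0, 1, 400)
        fv = np.sin(np.pi * u) + 0.5 * np.sin(5 * np.pi * u) ** 2
        assert classify_pattern(fv) == "multi_peak"

    def test_refuses_degenerate_input(self):
        with pytest.raises(ValueError):
            classify_pattern(np.zeros(100))

    def test_moderate_speed_solution_is_double_hump(self, stable_fixed_points):
        assert stable_fixed_points[0].pattern_label == "double_hump"


def _fake_fp(stable, pattern, ls, dzp=1e-4, p=1.0):
    point = SearchPoint(0.45, 0.6, p, -0.3, 50.0)
    return FixedPoint(search_point=point, poincare_state=PoincareState(0.99, 0.45),
                      deviation=dzp, stable=stable,
                      eigenvalue_magnitudes=(0.9, 0.5), pattern_label=pattern,
                      step_length=ls, step_duration=1.0, contact_time=1.2,
                      average_speed=0.45)


class TestSelection:
    def test_single_candidate(self):
        fp = _fake_fp(True, "double_hump", 0.7)
        assert select_solution([fp]) is fp

    def test_max_step_length_rule(self):
        a = _fake_fp(True, "double_hump", 0.71)
        b = _fake_fp(True, "double_hump", 0.74)
        assert select_solution([a, b]) is b

    def test_double_hump_preferred_over_longer_multi_peak(self):
        a = _fake_fp(True, "double_hump", 0.60)
        b = _fake_fp(True, "multi_peak", 0.80)
        assert select_solution([a, b]) is a

    def test_unstable_excluded_when_stable_exists(self):
        a = _fake_fp(True, "double_hump", 0.60)
        b = _fake_fp(False, "double_hump", 0.90)
        assert select_solution([a, b]) is a

    def test_multi_peak_fallback_warns(self):
        a = _fake_fp(True, "multi_peak", 0.5)
        b = _fake_fp(True, "multi_peak", 0.6)
        with pytest.warns(UserWarning, match="double-hump"):
            assert select_solution([a, b]) is b

    def test_empty_candidates_raise(self):
        with pytest.raises(NoSolutionError):
            select_solution([])

    def test_deterministic_tiebreak(self):
        a = _fake_fp(True, "double_hump", 0.7, dzp=1e-4, p=2.0)
        b = _fake_fp(True, "double_hump", 0.7, dzp=1e-5, p=3.0)
        assert select_solution([a, b]) is b


class TestRefinement:
    def test_refined_point_is_sharply_periodic(self, stable_fixed_points):
        fp = stable_fixed_points[0]
        params = NormalizedParameters(
            leg_stiffness=fp.search_point.leg_stiffness,
            touchdown_angle=fp.search_point.touchdown_angle)
        zp = refine_fixed_point(fp.poincare_state, params)
        zpR, _ = return_map(zp, params, record=False)
        dz = np.hypot(zpR.com_height - zp.com_height,
                      zpR.forward_speed - zp.forward_speed)
        assert dz < 1e-7

    def test_contact_time_matches_extraction(self, stable_fixed_points):
        """Event-based contact time agrees with threshold extraction."""
        fp = stable_fixed_points[0]
        params = NormalizedParameters(
            leg_stiffness=fp.search_point.leg_stiffness,
            touchdown_angle=fp.search_point.touchdown_angle)
        traj = simulate_step((fp.poincare_state.com_height,
                              fp.poincare_state.forward_speed), params)
        tau, fv, fap, _ = traj.stance_curves()
        fs = 1000.0
        grid = np.arange(0.0, tau[-1], 1.0 / fs)
        pad = np.zeros(50)
        trial = GRFTrial(sampling_rate=fs,
                         fv=np.concatenate([pad, np.interp(grid, tau, fv), pad]),
                         fap=np.concatenate([pad, np.interp(grid, tau, fap), pad]))
        summary = extract_summary(trial, threshold=1e-4)
        assert summary.contact_time == pytest.approx(traj.contact_time,
                                                     abs=3.0 / fs)
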