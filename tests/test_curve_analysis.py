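"""Baseline, origin, derivative, event detection and work integration."""

import numpy as np
import pytest

from ccfs import (
    AnalysisError,
    AnalysisParams,
    CurveMetadata,
    ForceCurve,
    RuptureEvent,
    analyze_curve,
    compute_detachment_work,
    detect_discontinuities,
    estimate_baseline,
    find_detachment_point,
    find_origin,
    make_staircase,
    smooth_derivative,
)

from conftest import flat_tail_curve


def curve_from(z, f):
    return ForceCurve(z=np.asarray(z, float), force=np.asarray(f, float), corrected=True)


class TestBaseline:
    def test_constant_force_level_zero_noise(self):
        z = np.linspace(0, 10, 200)
        level, sd = estimate_baseline(curve_from(z, np.full(200, 0.30)), 0.2)
        assert level == pytest.approx(0.30)
        assert sd == 0.0

    def test_adhesion_well_does_not_bias_flat_tail(self):
        c = flat_tail_curve()
        level, sd = estimate_baseline(c, 0.2)
        assert level == 0.0 and sd == 0.0

    def test_mad_scaled_noise_matches_sigma(self):
        rng = np.random.default_rng(11)
        z = np.linspace(0, 20, 2000)
        c = curve_from(z, rng.normal(0.0, 0.05, 2000))
        _, sd = estimate_baseline(c, 0.5)
        assert abs(sd - 0.05) / 0.05 < 0.15

    def test_tiny_window_is_analysis_error(self):
        z = np.linspace(0, 1, 64)
        with pytest.raises(AnalysisError, match="insufficient baseline"):
            estimate_baseline(curve_from(z, np.zeros(64)), 0.1)


class TestOrigin:
    def test_crossing_at_exact_sample(self):
        z = np.array([12.0, 12.2, 12.4, 12.6, 12.8])
        f = np.array([0.4, 0.2, 0.0, -0.2, -0.1])
        assert find_origin(curve_from(z, f), 0.0) == pytest.approx(12.4)

    def test_crossing_interpolated_between_samples(self):
        z = np.array([2.8, 3.0, 3.2, 3.4])
        f = np.array([0.3, -0.1, 0.1, 0.0])
        # first crossing in retraction order is between 2.8 and 3.0
        assert find_origin(curve_from(z, f), 0.0) == pytest.approx(2.95)
        f2 = np.array([0.5, 0.3, 0.1, -0.1])
        c2 = curve_from(np.array([2.6, 2.8, 3.0, 3.2]), f2)
        assert find_origin(c2, 0.0) == pytest.approx(3.1)

    def test_all_positive_curve_has_no_crossing(self):
        z = np.linspace(0, 5, 50)
        with pytest.raises(AnalysisError, match="no crossing"):
            find_origin(curve_from(z, 1.0 + z * 0.0), 0.0)


class TestSmoothDerivative:
    @pytest.mark.parametrize("slope", [2.0, -3.5])
    def test_linear_ramp_reproduced(self, slope):
        z = np.linspace(0, 1, 201)
        d = smooth_derivative(curve_from(z, slope * z), 21, 3)
        np.testing.assert_allclose(d[15:-15], slope, atol=1e-9)

    def test_quadratic_derivative_exact_away_from_edges(self):
        z = np.linspace(0, 1, 501)
        d = smooth_derivative(curve_from(z, z**2), 11, 2)
        np.testing.assert_allclose(d[10:-10], 2 * z[10:-10], atol=1e-6)

    def test_constant_force_zero_derivative(self):
        z = np.linspace(0, 1, 101)
        d = smooth_derivative(curve_from(z, np.full(101, 3.0)), 21, 3)
        np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_invalid_window_rejected(self):
        z = np.linspace(0, 1, 101)
        with pytest.raises(ValueError):
            smooth_derivative(curve_from(z, z), 20, 3)
        with pytest.raises(ValueError):
            smooth_derivative(curve_from(z, z), 5, 5)


class TestEventDetection:
    def _detect(self, curve, **kw):
        level, sd = estimate_baseline(curve, 0.2)
        d = smooth_derivative(curve, 21, 3)
        origin = find_origin(curve, level)
        return detect_discontinuities(
            curve, d, 5.0, sd, window=21, baseline_level=level, origin_z=origin, **kw
        )

    def test_smooth_decay_has_no_events(self):
        z = np.linspace(0, 30, 3000)
        f = np.where(z < 1.0, 1.0 - z, 0.0)
        f = f - np.where(z >= 1.0, np.exp(-(z - 1.0) / 3.0), 0.0)
        events = self._detect(curve_from(z, f))
        assert events == []

    def test_three_step_staircase_found_exactly(self):
        rng = np.random.default_rng(5)
        positions = np.array([6.0, 12.0, 18.0])
        c = make_staircase([0.4, 0.4, 0.4], positions, noise_sd=0.02, rng=rng)
        events = self._detect(c)
        assert len(events) == 3
        found = np.array([e.z_position for e in events]) + 1.0  # origin at contact_z=1
        span = 21 * np.mean(np.diff(c.z))
        assert np.all(np.abs(found - positions) <= span / 2)
        for e in events:
            assert 0.2 < e.force_jump < 0.6
            assert e.post_force > e.pre_force

    def test_step_at_noise_amplitude_rejected(self):
        rng = np.random.default_rng(6)
        c = make_staircase([0.02], [10.0], noise_sd=0.02, rng=rng)
        assert self._detect(c) == []

    def test_rupture_event_invariants_enforced(self):
        with pytest.raises(ValueError):
            RuptureEvent(z_position=1.0, force_jump=-0.1, pre_force=-0.5, post_force=-0.6)
        with pytest.raises(ValueError):
            RuptureEvent(z_position=1.0, force_jump=0.1, pre_force=-0.1, post_force=-0.5)


class TestDetachmentPoint:
    def _events(self, zs):
        return [
            RuptureEvent(z_position=z, force_jump=0.3, pre_force=-0.4, post_force=-0.1)
            for z in zs
        ]

    def test_last_event_selected(self):
        z_det, f_det = find_detachment_point(self._events([2.0, 5.5, 9.1]))
        assert z_det == 9.1 and f_det == -0.4

    def test_single_event(self):
        z_det, _ = find_detachment_point(self._events([4.2]))
        assert z_det == 4.2

    def test_empty_event_list_flagged(self):
        with pytest.raises(AnalysisError, match="no detachment"):
            find_detachment_point([])


class TestWork:
    def test_zero_force_zero_work(self):
        z = np.linspace(0, 5, 500)
        c = curve_from(z, np.zeros(500))
        assert compute_detachment_work(c, 4.0) == 0.0

    def test_triangular_well_area(self):
        # 0 -> -1 nN at 1 um -> 0 at 2 um: area = 1.0 fJ
        z = np.linspace(0, 4, 4001)
        f = np.where(z <= 1.0, -z, np.where(z <= 2.0, -(2.0 - z), 0.0))
        c = curve_from(z, f)
        assert compute_detachment_work(c, 2.0) == pytest.approx(1.0, rel=1e-9)

    def test_matches_oversampled_riemann_oracle(self):
        rng = np.random.default_rng(13)
        z = np.linspace(0, 10, 101)
        f = -np.abs(rng.normal(0, 1, 101))
        f[0] = f[-1] = 0.0
        c = curve_from(z, f)
        dense = np.union1d(np.linspace(0, 9.7, 100001), z[z <= 9.7])
        oracle = -np.trapezoid(np.interp(dense, z, f), dense)
        assert compute_detachment_work(c, 9.7) == pytest.approx(oracle, rel=1e-6)

    def test_z_det_beyond_last_sample_rejected(self):
        z = np.linspace(0, 5, 500)
        c = curve_from(z, np.zeros(500))
        with pytest.raises(AnalysisError):
            compute_detachment_work(c, 6.0)


class TestAnalyzeCurve:
    def test_simulator_ground_truth_recovered(self, simulated_curve):
        curve, truth = simulated_curve
        res = analyze_curve(curve)
        assert res.ok
        assert abs(res.work - truth.true_work) / truth.true_work < 0.05
        assert res.z_det <= truth.rupture_z[-1] - truth.true_origin + 0.25

    def test_flat_noise_only_curve_flagged_no_contact(self):
        rng = np.random.default_rng(3)
        z = np.linspace(0, 80, 4000)
        c = curve_from(z, rng.normal(0, 0.02, 4000))
        res = analyze_curve(c)
        assert not res.ok and "no contact" in res.flag

    def test_idempotent(self, simulated_curve):
        curve, _ = simulated_curve
        r1, r2 = analyze_curve(curve), analyze_curve(curve)
        assert r1.work == r2.work and r1.z_det == r2.z_det
        assert len(r1.events) == len(r2.events)

    def test_translation_invariance_of_results(self):
        rng = np.random.default_rng(21)
        c, _ = _stair_with_noise(rng)
        res0 = analyze_curve(c)
        shifted = ForceCurve(z=c.z, force=c.force + 0.7, metadata=c.metadata, corrected=True)
        res1 = analyze_curve(shifted)
        assert res1.ok and res0.ok
        assert res1.work == pytest.approx(res0.work, rel=1e-6)
        assert res1.z_det == pytest.approx(res0.z_det, abs=1e-9)
        assert len(res1.events) == len(res0.events)

    @pytest.mark.parametrize("c_scale", [0.5, 3.0])
    def test_force_scaling_scales_work_and_jumps(self, c_scale):
        rng = np.random.default_rng(22)
        c, _ = _stair_with_noise(rng)
        res0 = analyze_curve(c)
        scaled = ForceCurve(z=c.z, force=c.force * c_scale, metadata=c.metadata, corrected=True)
        res1 = analyze_curve(scaled)
        assert res1.ok
        assert res1.work == pytest.approx(c_scale * res0.work, rel=1e-6)
        assert len(res1.events) == len(res0.events)
        for e0, e1 in zip(res0.events, res1.events):
            assert e1.force_jump == pytest.approx(c_scale * e0.force_jump, rel=1e-6)

    @pytest.mark.parametrize("z_scale", [0.5, 2.0])
    def test_z_scaling_scales_work_and_z_det(self, z_scale):
        rng = np.random.default_rng(23)
        c, _ = _stair_with_noise(rng)
        res0 = analyze_curve(c)
        scaled = ForceCurve(z=c.z * z_scale, force=c.force, metadata=c.metadata, corrected=True)
        res1 = analyze_curve(scaled)
        assert res1.ok
        assert res1.work == pytest.approx(z_scale * res0.work, rel=1e-6)
        assert res1.z_det == pytest.approx(z_scale * res0.z_det, rel=1e-6)

    def test_events_never_beyond_z_det(self, simulated_curve):
        curve, _ = simulated_curve
        res = analyze_curve(curve)
        assert res.ok
        assert all(e.z_position <= res.z_det for e in res.events)
        assert res.z_det == res.events[-1].z_position
        assert res.max_adhesion >= abs(res.f_det) - 1e-9

    def test_short_curve_flagged(self):
        z = np.linspace(0, 1, 32)
        res = analyze_curve(curve_from(z, np.zeros(32)))
        assert not res.ok and "too short" in res.flag


def _stair_with_noise(rng):
    positions = np.array([5.0, 11.0, 17.0])
    c = make_staircase([0.5, 0.3, 0.4], positions, noise_sd=0.01, rng=rng)
    return c, positions
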