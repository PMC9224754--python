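import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gaitpipe.kinematics import (
    NormalizedCycle,
    cardan_angles,
    compose_cardan,
    deviation_flags,
    ensemble_stats,
    joint_angle_series,
    relative_rotation,
    time_normalize,
)


def random_rotation(rng):
    return Rotation.random(random_state=rng).as_matrix()


class TestRelativeRotation:
    def test_identical_poses_give_identity(self):
        r = random_rotation(np.random.default_rng(0))
        np.testing.assert_allclose(relative_rotation(r, r), np.eye(3),
                                   atol=1e-12)

    def test_identity_proximal_returns_distal(self):
        r = random_rotation(np.random.default_rng(1))
        np.testing.assert_allclose(relative_rotation(np.eye(3), r), r,
                                   atol=1e-12)

    def test_matches_elementwise_product_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p, d = random_rotation(rng), random_rotation(rng)
            oracle = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    oracle[i, j] = sum(p[k, i] * d[k, j] for k in range(3))
            np.testing.assert_allclose(relative_rotation(p, d), oracle,
                                       atol=1e-12)

    def test_accepts_homogeneous_transforms(self):
        t = np.eye(4)
        t[:3, :3] = random_rotation(np.random.default_rng(3))
        np.testing.assert_allclose(relative_rotation(t, t), np.eye(3),
                                   atol=1e-12)

    def test_non_finite_pose_rejected(self):
        bad = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            relative_rotation(bad, np.eye(3))


class TestCardanAngles:
    def test_identity_gives_zero(self):
        angles, gimbal = cardan_angles(np.eye(3))
        np.testing.assert_allclose(angles, 0.0, atol=1e-12)
        assert not gimbal

    def test_pure_flexion(self):
        r = compose_cardan(30.0, 0.0, 0.0)
        angles, _ = cardan_angles(r)
        np.testing.assert_allclose(angles, [30.0, 0.0, 0.0], atol=1e-9)

    @given(st.floats(-179.0, 179.0), st.floats(-80.0, 80.0),
           st.floats(-179.0, 179.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_on_principal_domain(self, a, b, c):
        r = compose_cardan(a, b, c)
        angles, gimbal = cardan_angles(r)
        assert not gimbal
        np.testing.assert_allclose(compose_cardan(*angles), r, atol=1e-9)

    def test_gimbal_proximity_flagged(self):
        _, gimbal = cardan_angles(compose_cardan(10.0, 90.0, 20.0))
        assert gimbal

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            cardan_angles(np.eye(3) * 2.0)

    def test_joint_curves_from_synthetic_track(self, session):
        track = session.mlmc[0].tracks[0]
        for joint in ("hip", "knee", "ankle"):
            curves = joint_angle_series(track, joint, "R")
            sag = curves["sagittal"].angles
            finite = sag[np.isfinite(sag)]
            assert finite.size > 0
            assert np.max(np.abs(finite)) < 180.0
        # knee flexion positive at its swing-phase peak
        knee = joint_angle_series(track, "knee", "R")["sagittal"].angles
        assert np.nanmax(knee) > 20.0

    def test_left_right_curves_superimpose(self, session):
        # symmetric gait + mirrored left conventions: L and R value ranges match
        track = session.mlmc[0].tracks[0]
        for joint in ("hip", "knee"):
            r = joint_angle_series(track, joint, "R")["sagittal"].angles
            l = joint_angle_series(track, joint, "L")["sagittal"].angles
            assert np.nanmax(r) == pytest.approx(np.nanmax(l), abs=2.0)
            assert np.nanmin(r) == pytest.approx(np.nanmin(l), abs=2.0)


class TestTimeNormalize:
    def test_constant_curve_stays_constant(self):
        nc = time_normalize(np.full(120, 7.5), 60.0, 0.2, 1.4, 0.9)
        np.testing.assert_allclose(nc.values, 7.5)

    def test_toe_off_marker_percent(self):
        nc = time_normalize(np.zeros(120), 60.0, 0.0, 1.0, 0.63)
        assert nc.toe_off_pct == pytest.approx(63.0)

    def test_linear_curve_linear_in_percent(self):
        t = np.arange(120) / 60.0
        nc = time_normalize(3.0 * t, 60.0, 0.2, 1.4, 0.8)
        expected = 3.0 * (0.2 + 1.2 * np.linspace(0, 1, 101))
        np.testing.assert_allclose(nc.values, expected, atol=1e-12)

    def test_uniform_time_scaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=240)
        a = time_normalize(x, 60.0, 0.5, 2.5, 1.7)
        b = time_normalize(x, 120.0, 0.25, 1.25, 0.85)  # same curve, 2x rate
        np.testing.assert_allclose(b.values, a.values, atol=1e-12)
        assert b.toe_off_pct == pytest.approx(a.toe_off_pct)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.zeros(100), 60.0, 0.5, 1.0, 1.2)


class TestEnsembleAndFlags:
    def _cycle(self, values, to=60.0):
        return NormalizedCycle(values=np.asarray(values, float), toe_off_pct=to)

    def test_identical_cycles_zero_sd(self):
        c = self._cycle(np.sin(np.linspace(0, 2 * np.pi, 101)))
        band = ensemble_stats([c, c, c])
        np.testing.assert_allclose(band.sd, 0.0, atol=1e-12)
        np.testing.assert_allclose(band.mean, c.values)

    def test_two_cycle_closed_form(self):
        base = np.linspace(-5, 5, 101)
        d = 2.5
        band = ensemble_stats([self._cycle(base + d), self._cycle(base - d)])
        np.testing.assert_allclose(band.mean, base, atol=1e-12)
        np.testing.assert_allclose(band.sd, d * np.sqrt(2), atol=1e-12)

    def test_band_converges_to_truth_mean(self):
        rng = np.random.default_rng(6)
        truth = 30.0 * np.sin(np.linspace(0, 2 * np.pi, 101))

        def band_error(n):
            cycles = [self._cycle(truth + rng.normal(0, 5, 101))
                      for _ in range(n)]
            return np.max(np.abs(ensemble_stats(cycles).mean - truth))

        assert band_error(400) < band_error(25)

    def test_fewer_than_two_cycles_rejected(self):
        with pytest.raises(ValueError):
            ensemble_stats([self._cycle(np.zeros(101))])

    def test_curve_on_mean_never_flagged(self):
        band = ensemble_stats([self._cycle(np.zeros(101) + d) for d in (-1, 1)])
        assert deviation_flags(self._cycle(np.zeros(101)), band, k_sd=1) == []

    def test_constant_exceedance_flags_whole_cycle(self):
        base = np.zeros(101)
        band = ensemble_stats([self._cycle(base + 1), self._cycle(base - 1)])
        flags = deviation_flags(self._cycle(base + 2 * band.sd[0] + 0.1),
                                band, k_sd=1)
        assert flags == [(0, 101)]

    def test_injected_midswing_deficit_flagged(self):
        truth = 30.0 * np.sin(np.linspace(0, 2 * np.pi, 101))
        rng = np.random.default_rng(7)
        band = ensemble_stats([self._cycle(truth + rng.normal(0, 1, 101))
                               for _ in range(20)])
        deficit = truth.copy()
        deficit[70:90] -= 20.0  # mid-swing knee-flexion deficit
        flags = deviation_flags(self._cycle(deficit), band, k_sd=2)
        assert any(a < 90 and b > 70 for a, b in flags)

    def test_flags_monotone_in_k_sd(self):
        rng = np.random.default_rng(8)
        truth = np.linspace(0, 10, 101)
        band = ensemble_stats([self._cycle(truth + rng.normal(0, 1, 101))
                               for _ in range(10)])
        curve = self._cycle(truth + rng.normal(0, 3, 101))

        def flagged_set(k):
            return {i for a, b in deviation_flags(curve, band, k_sd=k)
                    for i in range(a, b)}

        assert flagged_set(2.0) <= flagged_set(1.0) <= flagged_set(0.5)
        assert deviation_flags(curve, band, k_sd=np.inf) == []
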