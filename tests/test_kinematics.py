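"""Segment yaw estimation, angular velocity, gait speed."""

import numpy as np
import pytest

from turncoord.io_mocap import MarkerTrajectory
from turncoord.kinematics import (
    DegenerateTriadError,
    angular_velocity,
    gait_speed,
    lowpass,
    segment_yaw,
)

FS = 200.0

TRIAD = np.array([[0.1, 0.0, 0.02], [-0.05, 0.08, 0.0], [-0.05, -0.08, -0.01]])


def _rot_z(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _markers_from_angles(angles_deg, triad=TRIAD, pre=None, offset=(0, 0, 0)):
    """Marker trajectories of a triad rotated about z by the given angles.

    ``pre`` optionally right-multiplies an extra (constant or per-frame)
    rotation applied before the z rotation.
    """
    T = len(angles_deg)
    pos = np.empty((T, 3, 3))
    for t, a in enumerate(angles_deg):
        R = _rot_z(a)
        if pre is not None:
            R = R @ pre
        pos[t] = (R @ triad.T).T + np.asarray(offset)
    return [MarkerTrajectory(f"m{i}", pos[:, i, :], FS) for i in range(3)]


class TestSegmentYaw:
    def test_linear_ramp_recovered(self):
        angles = np.linspace(0.0, 90.0, 100)
        yaw = segment_yaw(_markers_from_angles(angles), "head")
        np.testing.assert_allclose(yaw.yaw_deg, angles, atol=1e-9)

    def test_pure_translation_gives_zero_yaw(self):
        T = 100
        shift = np.linspace(0, 3, T)
        pos = TRIAD[None] + np.column_stack([shift, shift / 2, 0 * shift])[:, None, :]
        markers = [MarkerTrajectory(f"m{i}", pos[:, i, :], FS) for i in range(3)]
        yaw = segment_yaw(markers, "head")
        np.testing.assert_allclose(yaw.yaw_deg, 0.0, atol=1e-9)

    def test_unwrap_through_180(self):
        angles = np.linspace(0.0, 190.0, 200)
        yaw = segment_yaw(_markers_from_angles(angles), "head")
        assert yaw.yaw_deg[-1] == pytest.approx(190.0, abs=1e-9)
        assert np.all(np.abs(np.diff(yaw.yaw_deg)) < 180.0)

    def test_composed_rotation_oracle(self):
        """Yaw of (10 deg about x, then 37 deg about z) is 37 degrees.

        Oracle: the rotation matrix is built explicitly and applied to the
        triad; the least-squares fit must extract the same z-angle.
        """
        angles = np.concatenate([np.zeros(5), np.full(5, 37.0)])
        markers = _markers_from_angles(angles, pre=None)
        # apply the x-rotation only on the later frames, composed before z
        pos = np.stack([m.positions for m in markers], axis=1)
        Rx = _rot_x(10.0)
        for t in range(5, 10):
            pos[t] = (_rot_z(37.0) @ Rx @ TRIAD.T).T
        markers = [MarkerTrajectory(f"m{i}", pos[:, i, :], FS) for i in range(3)]
        yaw = segment_yaw(markers, "head")
        assert yaw.yaw_deg[-1] == pytest.approx(37.0, abs=1e-6)

    def test_z_rotation_equivariance_and_translation_invariance(self):
        """Rotating the moving frames by alpha about z adds alpha to yaw.

        The reference (first) frame stays put, so the extra rotation must
        appear verbatim in the yaw signal; translating the whole marker set
        must change nothing.
        """
        rng = np.random.default_rng(5)
        angles = rng.uniform(-30, 30, 50).cumsum() / 10
        angles -= angles[0]
        base = segment_yaw(_markers_from_angles(angles), "head")
        for alpha in (17.0, -64.0):
            shifted = angles.copy()
            shifted[1:] += alpha
            yaw = segment_yaw(
                _markers_from_angles(shifted, offset=(1.2, -0.7, 0.4)), "head"
            )
            np.testing.assert_allclose(
                yaw.yaw_deg[1:], base.yaw_deg[1:] + alpha, atol=1e-9
            )

    def test_collinear_triad_rejected(self):
        collinear = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
        markers = _markers_from_angles(np.zeros(10), triad=collinear)
        with pytest.raises(DegenerateTriadError):
            segment_yaw(markers, "head")

    def test_fewer_than_three_markers_rejected(self):
        markers = _markers_from_angles(np.zeros(10))[:2]
        with pytest.raises(DegenerateTriadError):
            segment_yaw(markers, "head")

    def test_occluded_frames_yield_nan_yaw(self):
        markers = _markers_from_angles(np.zeros(30))
        markers[0].positions[10:25] = np.nan
        yaw = segment_yaw(markers, "head")
        assert np.isnan(yaw.yaw_deg[10:25]).all()
        assert yaw.valid[:10].all() and yaw.valid[25:].all()


class TestAngularVelocity:
    @staticmethod
    def _signal(yaw_deg):
        from turncoord.kinematics import SegmentYawSignal

        return SegmentYawSignal("head", np.asarray(yaw_deg, float), FS)

    def test_linear_ramp_rate(self):
        t = np.arange(1000) / FS
        omega = angular_velocity(self._signal(60.0 * t))
        np.testing.assert_allclose(omega.omega_degps[300:-300], 60.0, atol=1e-3)

    def test_constant_yaw_zero_rate(self):
        omega = angular_velocity(self._signal(np.full(500, 42.0)))
        np.testing.assert_allclose(omega.omega_degps, 0.0, atol=1e-9)

    def test_logistic_transition_peak_rate(self):
        """Peak rate of a logistic yaw matches its analytic derivative M*k/4."""
        M, duration = 180.0, 2.0
        k = 2.0 * np.log(19.0) / duration  # 5-95% span parameterization
        t = np.arange(2000) / FS - 5.0
        yaw = M / (1.0 + np.exp(-k * t))
        omega = angular_velocity(self._signal(yaw))
        assert np.max(omega.omega_degps) == pytest.approx(M * k / 4, rel=0.02)

    def test_time_reversal_antisymmetry(self):
        rng = np.random.default_rng(11)
        yaw = lowpass(rng.normal(size=3000).cumsum(), FS, 6.0)
        fwd = angular_velocity(self._signal(yaw)).omega_degps
        rev = angular_velocity(self._signal(yaw[::-1])).omega_degps
        np.testing.assert_allclose(rev[500:-500], -fwd[::-1][500:-500], atol=1e-6)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            angular_velocity(self._signal(np.zeros(100)), filter_cutoff_hz=100.0)


class TestGaitSpeed:
    @staticmethod
    def _pelvis(vel_x):
        T = 600
        x = np.arange(T) / FS * vel_x
        pos = np.column_stack([x, np.zeros(T), np.ones(T)])
        return [
            MarkerTrajectory(f"p{i}", pos + off, FS)
            for i, off in enumerate(([0.1, 0, 0], [-0.1, 0.05, 0], [0, -0.05, 0]))
        ]

    def test_constant_translation(self):
        assert gait_speed(self._pelvis(1.2), []) == pytest.approx(1.2, rel=1e-9)

    def test_stationary_pelvis(self):
        assert gait_speed(self._pelvis(0.0), []) == pytest.approx(0.0, abs=1e-12)

    def test_simulator_speed_recovered(self, nf_sim):
        trial, truth = nf_sim
        windows = list(
            zip(truth.turn_starts["pelvis"] - 0.6, truth.turn_ends["pelvis"] + 0.6)
        )
        speed = gait_speed(trial.segment_markers("pelvis"), windows)
        assert speed == pytest.approx(truth.gait_speed_mps, rel=0.05)

    def test_no_straight_interval_raises(self):
        with pytest.raises(ValueError, match="straight"):
            gait_speed(self._pelvis(1.0), [(-(1.0), 10.0)])
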