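import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitpath.imu_io import GRAVITY, ImuSeries
from gaitpath.synthetic_gait import (
    CohortSpec,
    SensorNoise,
    orientation_series,
    render_imu,
    simulate_session,
)
from gaitpath.trajectory_estimation import (
    DegenerateStrideError,
    DetectorConfig,
    EstimatorConfig,
    NotQuasiStaticError,
    dedrift_integrate,
    detect_heel_strikes,
    estimate_initial_orientation,
    estimate_trajectories,
    propagate_orientation,
    rotate_to_stride_frame,
    segment_strides,
    world_acceleration,
)
from tests.conftest import match_strides

FS = 100.0


class TestDetectHeelStrikes:
    def test_zero_signal_empty(self):
        assert len(detect_heel_strikes(np.zeros(500), FS)) == 0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_heel_strikes(np.zeros(100), FS)

    def test_refractory_keeps_larger_of_close_spikes(self):
        t = np.arange(0, 10, 1 / FS)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, len(t))  # background so the MAD scale is sane

        def spike(center, amp):
            m = np.abs(t - center) < 0.04
            x[m] += amp * 0.5 * (1 + np.cos(np.pi * (t[m] - center) / 0.04))

        spike(4.0, 3.0)
        spike(4.2, 6.0)  # 0.2 s apart < 0.6 s refractory
        idx = detect_heel_strikes(x, FS, DetectorConfig(band_hz=(0.5, 20)))
        assert len(idx) == 1
        assert t[idx[0]] == pytest.approx(4.2, abs=0.05)

    def test_synthetic_session_recovery(self, noisy_session):
        session, truth = noisy_session
        det = session.left.time[detect_heel_strikes(session.left.gyro[:, 2], FS)]
        true_hs = truth.heel_strikes("left")
        hits = sum(np.min(np.abs(det - t)) < 0.030 for t in true_hs)
        assert hits / len(true_hs) >= 0.95


class TestSegmentStrides:
    def test_fencepost(self, quiet_session):
        session, _ = quiet_session
        hs = detect_heel_strikes(session.left.gyro[:, 2], FS)
        segments = segment_strides(session.left, hs)
        assert len(segments) == len(hs) - 1

    def test_partition_property(self, quiet_session):
        session, _ = quiet_session
        hs = detect_heel_strikes(session.left.gyro[:, 2], FS)
        segments = segment_strides(session.left, hs)
        for a, b in zip(segments[:-1], segments[1:]):
            assert a.end_index == b.start_index
        assert segments[0].start_index == hs[0]
        assert segments[-1].end_index == hs[-1]

    def test_fewer_than_two_heel_strikes(self, quiet_session):
        session, _ = quiet_session
        assert segment_strides(session.left, [100]) == []

    def test_midstance_close_to_truth(self, quiet_session):
        session, truth = quiet_session
        hs = detect_heel_strikes(session.left.gyro[:, 2], FS)
        segments = segment_strides(session.left, hs)
        true_ms = np.array([r.mid_stance_t for r in truth.strides["left"]])
        for seg in segments:
            t_ms = session.left.time[seg.mid_stance_index]
            assert np.min(np.abs(true_ms - t_ms)) < 0.050


class TestInitialOrientation:
    def test_aligned_sensor_identity(self):
        r = estimate_initial_orientation(np.array([0.0, 0.0, GRAVITY]))
        np.testing.assert_allclose(r.apply([0, 0, GRAVITY]), [0, 0, GRAVITY], atol=1e-9)

    def test_tilted_10deg_self_consistency(self):
        tilt = Rotation.from_euler("y", np.deg2rad(10))
        measured = tilt.inv().apply([0, 0, GRAVITY])
        r = estimate_initial_orientation(measured)
        np.testing.assert_allclose(r.apply(measured), [0, 0, GRAVITY], atol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(NotQuasiStaticError):
            estimate_initial_orientation(np.zeros(3))

    def test_non_quasi_static_norm_rejected(self):
        with pytest.raises(NotQuasiStaticError):
            estimate_initial_orientation(np.array([0, 0, 1.5 * GRAVITY]))


class TestPropagateOrientation:
    def test_zero_gyro_constant(self):
        init = Rotation.from_euler("y", 0.3)
        out = propagate_orientation(np.zeros((50, 3)), init, 25, FS)
        np.testing.assert_allclose(
            (out[0].inv() * out[-1]).magnitude(), 0.0, atol=1e-12
        )
        np.testing.assert_allclose((init.inv() * out[10]).magnitude(), 0, atol=1e-12)

    def test_constant_rate_closed_form(self):
        omega = 0.7  # rad/s about sensor z
        n = 201
        gyro = np.tile([0.0, 0.0, omega], (n, 1))
        out = propagate_orientation(gyro, Rotation.identity(), 0, 1000.0)
        expected = omega * (n - 1) / 1000.0
        assert out[-1].magnitude() == pytest.approx(expected, abs=1e-6)

    def test_reversed_gyro_returns_to_init(self):
        rng = np.random.default_rng(3)
        gyro = rng.normal(0, 2, (100, 3))
        init = Rotation.from_euler("xyz", [0.1, -0.2, 0.3])
        fwd = propagate_orientation(gyro, init, 0, FS)
        # integrating the time-reversed, sign-flipped rates from the end
        back = propagate_orientation(-gyro[::-1], fwd[-1], 0, FS)
        np.testing.assert_allclose(
            (back[-1].inv() * init).magnitude(), 0.0, atol=1e-9
        )


class TestWorldAcceleration:
    def test_static_zero(self):
        n = 10
        orient = Rotation.identity(n)
        accel = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        np.testing.assert_allclose(world_acceleration(accel, orient), 0.0, atol=1e-12)

    def test_norm_preserved_before_gravity_subtraction(self):
        rng = np.random.default_rng(0)
        accel = rng.normal(0, 3, (20, 3))
        orient = Rotation.random(20, rng=1)
        rotated = world_acceleration(accel, orient) + [0, 0, GRAVITY]
        np.testing.assert_allclose(
            np.linalg.norm(rotated, axis=1), np.linalg.norm(accel, axis=1), atol=1e-9
        )

    def test_generator_oracle_with_true_orientation(self, profiles):
        from gaitpath.synthetic_gait import StrideParams, simulate_stride_kinematics

        p = StrideParams(1.2, 0.15, 0.05, 0.07, 1.1)
        kin = simulate_stride_kinematics(p, FS)
        noise = SensorNoise(0, 0, (0, 0, 0), (0, 0, 0), hs_spike_amplitude=0.0)
        series = render_imu(kin, noise, seed=0)
        orient = orientation_series(kin)
        a_w = world_acceleration(series.accel, orient)
        np.testing.assert_allclose(a_w, kin.acceleration, atol=1e-6)


class TestDedriftIntegrate:
    def test_zero_accel(self):
        v, p = dedrift_integrate(np.zeros((100, 3)), FS)
        np.testing.assert_allclose(v, 0, atol=1e-15)
        np.testing.assert_allclose(p, 0, atol=1e-15)

    def test_constant_bias_cancels_exactly(self):
        c = 0.37
        n = 120
        v, p = dedrift_integrate(np.full((n, 1), c), FS)
        # (1 - t/T) c t + (t/T) c (t - T) = 0 for every t
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_sine_closed_form(self):
        # a(t) = A sin(2 pi t / T): v(0) = v(T) = 0 holds for the true motion
        T, A = 1.0, 1.0
        n = int(T * FS) + 1
        t = np.linspace(0, T, n)
        a = A * np.sin(2 * np.pi * t / T)
        w = 2 * np.pi / T
        true_v = A / w * (1 - np.cos(w * t))
        true_p = A / w * (t - np.sin(w * t) / w)
        v, p = dedrift_integrate(a[:, None], FS)
        np.testing.assert_allclose(v[:, 0], true_v, atol=1e-3)
        np.testing.assert_allclose(p[:, 0], true_p, atol=1e-4)

    def test_too_short_raises(self):
        with pytest.raises(Exception):
            dedrift_integrate(np.zeros((3, 3)), FS)

    def test_endpoint_constraints_exact(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 3, (150, 3))
        v, p = dedrift_integrate(a, FS)
        np.testing.assert_allclose(v[0], 0, atol=1e-12)
        np.testing.assert_allclose(v[-1], 0, atol=1e-12)
        assert p[0, 2] == pytest.approx(0, abs=1e-12)
        assert p[-1, 2] == pytest.approx(0, abs=1e-12)


class TestStrideFrame:
    def _traj(self):
        n = 50
        t = np.arange(n) / FS
        pos = np.zeros((n, 3))
        pos[:, 0] = np.linspace(0, 1.2, n)
        pos[:, 2] = 0.1 * np.sin(np.pi * np.linspace(0, 1, n))
        vel = np.gradient(pos, t, axis=0)
        return t, pos, vel

    def test_displacement_along_x(self):
        t, pos, vel = self._traj()
        traj = rotate_to_stride_frame(t, pos, vel)
        np.testing.assert_allclose(traj.position[:, 0], pos[:, 0], atol=1e-12)
        np.testing.assert_allclose(traj.position[:, 1], 0, atol=1e-12)

    def test_rotation_invariance(self):
        t, pos, vel = self._traj()
        base = rotate_to_stride_frame(t, pos, vel)
        ang = np.deg2rad(37)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = rotate_to_stride_frame(t, pos @ rot.T, vel @ rot.T)
        np.testing.assert_allclose(rotated.position, base.position, atol=1e-9)

    def test_zero_displacement_raises(self):
        n = 20
        t = np.arange(n) / FS
        with pytest.raises(DegenerateStrideError):
            rotate_to_stride_frame(t, np.zeros((n, 3)), np.zeros((n, 3)))


class TestEstimateTrajectories:
    def test_noise_free_stride_length_within_1pct(self, quiet_session):
        session, truth = quiet_session
        res = estimate_trajectories(session)
        for side in ("left", "right"):
            for rec, _seg, traj in match_strides(session, truth, res, side):
                rel = abs(traj.stride_length - rec.params.stride_length)
                assert rel / rec.params.stride_length < 0.01

    def test_static_recording_yields_nothing(self):
        n = 2000
        t = np.arange(n) / FS
        accel = np.tile([0, 0, GRAVITY], (n, 1))
        series_l = ImuSeries("left", t, accel, np.zeros((n, 3)))
        series_r = ImuSeries("right", t, accel.copy(), np.zeros((n, 3)))
        from gaitpath.imu_io import SensorSpec, WalkSession

        session = WalkSession("p", "mild_pd", series_l, series_r, SensorSpec())
        res = estimate_trajectories(session)
        assert all(len(r["trajectories"]) == 0 for r in res.values())
        assert all(len(r["dropped"]) >= 1 for r in res.values())

    def test_sampling_rate_doubling_stable(self, profiles):
        spec100 = CohortSpec(strides_per_session=16, n_turns=0, sampling_rate=100.0)
        spec200 = CohortSpec(strides_per_session=16, n_turns=0, sampling_rate=200.0)
        lengths = {}
        for fs, spec in ((100.0, spec100), (200.0, spec200)):
            session, truth = simulate_session(
                profiles["healthy_older"], spec, seed=11, noise=SensorNoise.silent()
            )
            res = estimate_trajectories(session)
            matched = match_strides(session, truth, res, "left")
            lengths[fs] = {rec.index: traj.stride_length for rec, _s, traj in matched
                           if rec.index != 0 and not rec.is_final}
        common = set(lengths[100.0]) & set(lengths[200.0])
        assert len(common) >= 7
        rel = [
            abs(lengths[200.0][k] - lengths[100.0][k]) / lengths[100.0][k]
            for k in common
        ]
        assert np.median(rel) < 0.005
        assert max(rel) < 0.01

    def test_bias_rejection(self, profiles):
        spec = CohortSpec(strides_per_session=10, n_turns=0)
        lengths = {}
        for tag, noise in (
            ("clean", SensorNoise.silent()),
            ("biased", SensorNoise(0, 0, (0.05, 0.0, 0.03), (0, 0, 0))),
        ):
            session, truth = simulate_session(
                profiles["healthy_older"], spec, seed=12, noise=noise
            )
            res = estimate_trajectories(session)
            matched = match_strides(session, truth, res, "left")
            lengths[tag] = {rec.index: traj.stride_length for rec, _s, traj in matched}
        for k in set(lengths["clean"]) & set(lengths["biased"]):
            assert (
                abs(lengths["biased"][k] - lengths["clean"][k]) / lengths["clean"][k]
                < 0.02
            )

    def test_session_yaw_invariance(self, profiles):
        """Rotating the whole world about the vertical axis leaves the
        stride-frame features untouched."""
        from gaitpath.synthetic_gait import StrideParams, simulate_stride_kinematics

        p = StrideParams(1.2, 0.15, 0.05, 0.07, 1.1)
        kin = simulate_stride_kinematics(p, FS)
        noise = SensorNoise.silent()
        base_series = render_imu(kin, noise, seed=0)

        ang = 0.8
        rot2 = np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        yawed = dataclasses.replace(
            kin,
            position=np.column_stack([kin.position[:, :2] @ rot2.T, kin.position[:, 2]]),
            velocity=np.column_stack([kin.velocity[:, :2] @ rot2.T, kin.velocity[:, 2]]),
            acceleration=np.column_stack(
                [kin.acceleration[:, :2] @ rot2.T, kin.acceleration[:, 2]]
            ),
            heading=kin.heading + ang,
        )
        yawed_series = render_imu(yawed, noise, seed=0)
        # the sensor-frame signals are identical up to the yaw of the world
        # frame, so the estimated stride-local trajectories must agree
        from gaitpath.trajectory_estimation import StrideSegment, estimate_stride

        def run(series):
            n = len(series)
            anchor = int(np.argmin(np.abs(series.gyro[n // 20: n // 2, 2]))) + n // 20
            seg = StrideSegment("left", 0, n - 1, 0, anchor)
            return estimate_stride(series, seg, FS, EstimatorConfig())

        t1 = run(base_series)
        t2 = run(yawed_series)
        np.testing.assert_allclose(t1.position, t2.position, atol=1e-6)
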