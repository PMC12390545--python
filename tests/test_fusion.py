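from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitsense.fusion import (
    FusionConfig,
    FusionState,
    evaluate_distance,
    kalman_gain,
    latlon_to_local,
    local_to_latlon,
    make_matrices,
    predict,
    run_fusion,
    update,
)
from gaitsense.sensor_io import GpsFix, SensorTrace
from gaitsense.synthetic_gait import (
    DEFAULT_ORIGIN,
    default_profiles,
    generate_gps,
    generate_trace,
)


class TestMakeMatrices:
    def test_control_matrix_values(self):
        _, B = make_matrices(0.01)
        assert B[0, 0] == pytest.approx(5e-5)
        assert B[1, 0] == pytest.approx(0.01)

    def test_unit_velocity_advances_position(self):
        A, _ = make_matrices(1.0)
        np.testing.assert_allclose(A @ [0, 1, 0, 0], [1, 1, 0, 0])

    @pytest.mark.parametrize("dt", [0.01, 0.1, 1.0, 2.5])
    def test_xy_block_symmetry(self, dt):
        A, B = make_matrices(dt)
        np.testing.assert_array_equal(A[:2, :2], A[2:, 2:])
        np.testing.assert_array_equal(A[:2, 2:], np.zeros((2, 2)))
        np.testing.assert_array_equal(B[:2, 0], B[2:, 1])

    def test_nonpositive_dt(self):
        with pytest.raises(ValueError):
            make_matrices(0.0)


class TestPredict:
    def test_kinematics_from_rest(self):
        cfg = FusionConfig(dt=1.0)
        out = predict(FusionState(X=np.zeros(4)), (1.0, 0.0), cfg)
        np.testing.assert_allclose(out.X, [0.5, 1.0, 0.0, 0.0])

    def test_constant_velocity_without_input(self):
        cfg = FusionConfig(dt=0.5)
        out = predict(FusionState(X=[2.0, 3.0, -1.0, 0.5]), (0, 0), cfg)
        assert out.X[0] == pytest.approx(2.0 + 3.0 * 0.5)
        assert out.X[2] == pytest.approx(-1.0 + 0.5 * 0.5)

    def test_process_noise_floor(self):
        cfg = FusionConfig(dt=0.01)
        st = FusionState(P=np.zeros((4, 4)))
        np.testing.assert_allclose(predict(st, (0, 0), cfg).P, 0.1 * np.eye(4))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            predict(FusionState(), (np.nan, 0.0), FusionConfig())


class TestUpdate:
    def test_initial_position_gain(self):
        cfg = FusionConfig()
        K = kalman_gain(FusionState(P=300.0 * np.eye(4)), cfg)
        assert abs(K[0, 0] - 300.0 / 305.01) < 1e-12
        assert abs(K[2, 1] - 300.0 / 305.01) < 1e-12

    def test_zero_innovation_keeps_state_and_shrinks_p(self):
        st = FusionState(X=[1.0, 0.5, -2.0, 0.1])
        out = update(st, (1.0, -2.0), FusionConfig())
        np.testing.assert_allclose(out.X, st.X, atol=1e-12)
        assert out.P[0, 0] < st.P[0, 0]

    def test_infinite_measurement_noise_is_no_information(self):
        cfg = FusionConfig(R=1e12 * np.eye(2))
        st = FusionState(X=[1.0, 0.5, -2.0, 0.1])
        out = update(st, (50.0, 50.0), cfg)
        np.testing.assert_allclose(out.X, st.X, atol=1e-6)


def _random_psd(rng, scale=10.0):
    m = rng.normal(size=(4, 4))
    return scale * (m @ m.T) / 4.0 + 1e-6 * np.eye(4)


def test_covariance_stays_symmetric_psd_and_update_contracts(rng):
    cfg = FusionConfig()
    for _ in range(20):
        st = FusionState(P=_random_psd(rng))
        for _ in range(10):
            if rng.random() < 0.5:
                st = predict(st, rng.normal(size=2), cfg)
            else:
                before = st.P[0, 0]
                st = update(st, rng.normal(scale=5.0, size=2), cfg)
                assert st.P[0, 0] <= before + 1e-12
            np.testing.assert_allclose(st.P, st.P.T, atol=1e-9)
            assert np.min(np.linalg.eigvalsh(st.P)) >= -1e-9


class TestRunFusion:
    def test_matches_double_integration_oracle(self, profiles):
        trace, _ = generate_trace(profiles["pocket"], duration_s=5, seed=7)
        cfg = FusionConfig(dt=0.01, Q=np.zeros((4, 4)))
        res = run_fusion(trace, config=cfg)

        rot = Rotation.from_quat(trace.meta.device_to_world)
        acc = (rot.apply(trace.acc) - cfg.gravity)[:, :2]
        x = np.zeros(2)
        v = np.zeros(2)
        oracle = [x.copy()]
        for k in range(1, len(trace)):
            u = acc[k - 1]
            x = x + v * 0.01 + 0.5 * u * 0.01**2
            v = v + u * 0.01
            oracle.append(x.copy())
        oracle = np.array(oracle)
        scale = max(1.0, np.abs(oracle).max())
        assert np.abs(res.trajectory - oracle).max() / scale < 1e-9

    def test_stationary_trace_without_gps_has_zero_distance(self):
        n = 200
        acc = np.zeros((n, 3))
        acc[:, 2] = 9.80665  # gravity only
        trace = SensorTrace(
            time_ms=np.arange(n) * 10.0,
            acc=acc, gyro=np.zeros((n, 3)), mag=np.zeros((n, 3)),
        )
        res = run_fusion(trace, config=FusionConfig(dt=0.01))
        assert res.distance_m == pytest.approx(0.0, abs=1e-12)

    def test_clean_walk_distance_within_one_percent(self, profiles):
        p = replace(profiles["pocket"], mag_std=0.0, acc_bias_std=0.0,
                    walk_speed=1.4)
        trace, truth = generate_trace(p, duration_s=60, fs_hz=100, seed=3)
        trace.gps = generate_gps(truth, DEFAULT_ORIGIN, 1.0, 0.0, seed=3)
        res = run_fusion(trace, config=FusionConfig(dt=0.01))
        assert res.distance_m == pytest.approx(84.0, rel=0.01)
        mae, rmse, err = evaluate_distance(res, truth)
        assert err < 0.01

    def test_grid_mismatch_rejected(self, profiles):
        trace, _ = generate_trace(profiles["pocket"], duration_s=2, seed=0)
        with pytest.raises(ValueError, match="resample"):
            run_fusion(trace, config=FusionConfig(dt=0.02))

    def test_beats_gps_only_and_dead_reckoning(self, profiles):
        """Fusing corrects dead-reckoning drift and smooths uncorrelated
        GPS jitter below the raw piecewise-linear fix distance."""
        from gaitsense.sensor_io import resample

        fused, gps_only, dead_reckoning = [], [], []
        for seed in range(10):
            trace, truth = generate_trace(
                profiles["pocket"], duration_s=60, fs_hz=100, seed=300 + seed
            )
            trace.gps = generate_gps(
                truth, DEFAULT_ORIGIN, 1.0, 3.0, seed=400 + seed,
                corr_time_s=0.0,
            )
            xy = np.array(
                [latlon_to_local(f, DEFAULT_ORIGIN) for f in trace.gps]
            )
            gps_len = np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1))
            gps_only.append(abs(gps_len - truth.total_distance))

            no_gps = SensorTrace(trace.time_ms, trace.acc, trace.gyro,
                                 trace.mag, meta=trace.meta)
            dr = run_fusion(no_gps, config=FusionConfig(dt=0.01))
            dead_reckoning.append(abs(dr.distance_m - truth.total_distance))

            res = run_fusion(resample(trace, 0.1), config=FusionConfig(dt=0.1))
            fused.append(abs(res.distance_m - truth.total_distance))
        assert np.mean(fused) < np.mean(gps_only)
        assert np.mean(fused) < np.mean(dead_reckoning)


class TestProjection:
    def test_origin_maps_to_zero(self):
        fix = GpsFix(0, *DEFAULT_ORIGIN)
        np.testing.assert_allclose(latlon_to_local(fix, DEFAULT_ORIGIN), 0.0)

    def test_one_meter_north(self):
        from gaitsense.fusion import EARTH_RADIUS_M

        lat = DEFAULT_ORIGIN[0] + np.degrees(1.0 / EARTH_RADIUS_M)
        xy = latlon_to_local((lat, DEFAULT_ORIGIN[1]), DEFAULT_ORIGIN)
        assert xy[1] == pytest.approx(1.0, abs=1e-9)
        assert xy[0] == pytest.approx(0.0, abs=1e-12)

    def test_roundtrip_identity(self, rng):
        pts = rng.uniform(-500, 500, size=(50, 2))
        lat, lon = local_to_latlon(pts, DEFAULT_ORIGIN)
        back = np.array([
            latlon_to_local((la, lo), DEFAULT_ORIGIN)
            for la, lo in zip(lat, lon)
        ])
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            latlon_to_local((DEFAULT_ORIGIN[0] + 2.0, DEFAULT_ORIGIN[1]),
                            DEFAULT_ORIGIN)


class TestEvaluateDistance:
    def test_perfect_prediction(self):
        t = np.linspace(0, 10, 11)
        d = 1.4 * t
        mae, rmse, err = evaluate_distance((t, d), (t, d))
        assert (mae, rmse, err) == (0.0, 0.0, 0.0)

    def test_hand_computed_errors(self):
        t = np.array([0.0, 1.0])
        mae, rmse, err = evaluate_distance(
            (t, np.array([3.0, 7.0])), (t, np.array([0.0, 10.0]))
        )
        assert mae == pytest.approx(3.0)
        assert rmse == pytest.approx(3.0)

    def test_error_rate_arithmetic(self):
        t = np.array([0.0, 1.0])
        _, _, err = evaluate_distance(
            (t, np.array([0.0, 102.55])), (t, np.array([0.0, 100.0]))
        )
        assert err == pytest.approx(0.0255)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_distance((np.array([]), np.array([])),
                              (np.array([0.0]), np.array([0.0])))
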