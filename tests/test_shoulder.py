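"""Shoulder kinematics: angle extraction, socket-ball vs bi-articular models,
parameter identification, trunk removal, reach discrimination."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wearkin import synth
from wearkin.shoulder import (
    ArmAngles,
    CalibrationMovement,
    ReachConfig,
    arm_direction,
    biarticular_position,
    classify_reach,
    extract_arm_angles,
    identify_parameters,
    remove_trunk_motion,
    socket_ball_position,
)
from wearkin.timeseries import OrientationStream


def _stream(rot, rate=100.0, seg=""):
    n = len(rot)
    return OrientationStream.from_rotation(np.arange(n) / rate, rot, rate, seg)


class TestExtractArmAngles:
    def test_identical_streams_zero_angles(self):
        rng = np.random.default_rng(0)
        rot = Rotation.from_rotvec(rng.normal(size=(20, 3)))
        angles = extract_arm_angles(_stream(rot), _stream(rot))
        np.testing.assert_allclose(angles.theta_deg, 0.0, atol=1e-9)
        np.testing.assert_allclose(angles.psi_deg, 0.0, atol=1e-7)

    def test_ninety_degree_frontal_abduction(self):
        n = 5
        sternum = Rotation.identity(n)
        # rotate about the antero-posterior (x) axis: pure frontal-plane elevation
        arm = Rotation.from_euler("x", np.full((n, 1), 90.0), degrees=True)
        angles = extract_arm_angles(_stream(arm), _stream(sternum))
        np.testing.assert_allclose(angles.psi_deg, 90.0, atol=1e-9)
        np.testing.assert_allclose(angles.theta_deg, 0.0, atol=1e-9)

    def test_invariant_to_common_world_rotation(self):
        rng = np.random.default_rng(1)
        sternum = Rotation.from_rotvec(rng.normal(size=(30, 3)) * 0.3)
        arm = sternum * Rotation.from_euler(
            "zx", np.column_stack([-rng.uniform(0, 90, 30), rng.uniform(5, 150, 30)]),
            degrees=True,
        )
        base = extract_arm_angles(_stream(arm), _stream(sternum))
        world = Rotation.from_rotvec([0.4, -0.2, 0.9])
        rotated = extract_arm_angles(_stream(world * arm), _stream(world * sternum))
        np.testing.assert_allclose(rotated.theta_deg, base.theta_deg, atol=1e-8)
        np.testing.assert_allclose(rotated.psi_deg, base.psi_deg, atol=1e-8)

    def test_mismatched_lengths_rejected(self):
        r1 = Rotation.identity(5)
        r2 = Rotation.identity(6)
        with pytest.raises(ValueError, match="mismatch"):
            extract_arm_angles(_stream(r1), _stream(r2))


class TestSocketBall:
    def test_rest_pose_hangs_below_center(self):
        angles = ArmAngles(t=[0.0], theta_deg=[0.0], psi_deg=[0.0])
        pos = socket_ball_position(angles, 0.3, [0.0, 0.2, 0.1])
        np.testing.assert_allclose(pos[0], [0.0, 0.2, 0.1 - 0.3], atol=1e-12)

    def test_constant_distance_from_center(self):
        rng = np.random.default_rng(2)
        n = 1000
        angles = ArmAngles(
            t=np.arange(n), theta_deg=rng.uniform(-180, 180, n),
            psi_deg=rng.uniform(0, 180, n),
        )
        pos = socket_ball_position(angles, 0.3, [0.0, 0.2, 0.1])
        radii = np.linalg.norm(pos - np.array([0.0, 0.2, 0.1]), axis=1)
        np.testing.assert_allclose(radii, 0.3, atol=1e-12)

    def test_abduction_sweep_traces_circle(self):
        psi = np.linspace(0, 150, 50)
        angles = ArmAngles(t=np.arange(50), theta_deg=np.zeros(50), psi_deg=psi)
        pos = socket_ball_position(angles, 0.3, [0.0, 0.0, 0.0])
        assert np.allclose(pos[:, 0], 0.0, atol=1e-12)  # stays in frontal plane
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1), 0.3, atol=1e-12)

    def test_nonpositive_length_rejected(self):
        angles = ArmAngles(t=[0.0], theta_deg=[0.0], psi_deg=[0.0])
        with pytest.raises(ValueError, match="L must be"):
            socket_ball_position(angles, 0.0, [0, 0, 0])


class TestBiarticularMap:
    def test_rest_strain_reduces_to_socket_ball(self, clean_shoulder):
        ds, sc = clean_shoulder
        params = ds.true_params
        rng = np.random.default_rng(3)
        n = 200
        angles = ArmAngles(
            t=np.arange(n), theta_deg=rng.uniform(0, 120, n),
            psi_deg=rng.uniform(0, 150, n),
        )
        bi = biarticular_position(angles, np.full(n, params.s0), params)
        sb = socket_ball_position(angles, params.L, params.p0)
        np.testing.assert_allclose(bi, sb, atol=1e-12)

    def test_humerus_length_conserved(self, clean_shoulder):
        ds, sc = clean_shoulder
        params = ds.true_params
        m = ds.frontal
        centers = biarticular_position(
            m.angles_true, m.strain.single(), params
        ) - params.L * arm_direction(m.angles_true.theta_deg, m.angles_true.psi_deg)
        pos = biarticular_position(m.angles_true, m.strain.single(), params)
        np.testing.assert_allclose(
            np.linalg.norm(pos - centers, axis=1), params.L, atol=1e-12
        )

    def test_full_arc_displacement_equals_chord(self, clean_shoulder):
        ds, sc = clean_shoulder
        params = ds.true_params
        angles = ArmAngles(t=[0.0], theta_deg=[0.0], psi_deg=[150.0])
        s_max = params.s0 + np.deg2rad(params.frontal_path.phi_max_deg) / params.strain_gain
        bi = biarticular_position(angles, np.array([s_max]), params)
        sb = socket_ball_position(angles, params.L, params.p0)
        assert np.linalg.norm(bi - sb) == pytest.approx(
            params.frontal_path.chord_length(), abs=1e-12
        )

    def test_strain_clipped_beyond_identified_arc(self, clean_shoulder):
        ds, _ = clean_shoulder
        params = ds.true_params
        angles = ArmAngles(t=[0.0], theta_deg=[0.0], psi_deg=[150.0])
        s_max = params.s0 + np.deg2rad(params.frontal_path.phi_max_deg) / params.strain_gain
        at_max = biarticular_position(angles, np.array([s_max]), params)
        beyond = biarticular_position(angles, np.array([s_max * 10]), params)
        np.testing.assert_allclose(beyond, at_max, atol=1e-12)


class TestIdentification:
    def test_noise_free_recovery_is_exact(self, clean_shoulder):
        ds, sc = clean_shoulder
        params = identify_parameters(ds.frontal.calibration(), ds.sagittal.calibration())
        assert params.L == pytest.approx(sc.L, rel=1e-9)
        np.testing.assert_allclose(params.p0, sc.p0, atol=1e-9)
        for m in (ds.frontal, ds.sagittal):
            rec = biarticular_position(m.angles_true, m.strain.single(), params)
            assert np.abs(rec - m.gold).max() < 1e-9

    def test_recovery_under_2mm_gold_noise(self, noisy_gold_shoulder):
        ds, sc = noisy_gold_shoulder
        params = identify_parameters(ds.frontal.calibration(), ds.sagittal.calibration())
        assert params.L == pytest.approx(sc.L, rel=0.01)
        assert params.frontal_path.a == pytest.approx(sc.frontal_arc[0], rel=0.10)
        assert params.frontal_path.b == pytest.approx(sc.frontal_arc[1], rel=0.10)
        assert params.sagittal_path.a == pytest.approx(sc.sagittal_arc[0], rel=0.10)
        assert params.sagittal_path.b == pytest.approx(sc.sagittal_arc[1], rel=0.10)

    def test_socket_ball_world_degenerates_to_point_arcs(self):
        sc = synth.ShoulderScenario(
            rhythm_split=0.0, flexion_split=0.0,
            noise=synth.NoiseModel(orient_deg=0.0, strain_ohm=0.0, gold_m=0.0),
        )
        ds = synth.gen_shoulder(sc)
        params = identify_parameters(ds.frontal.calibration(), ds.sagittal.calibration())
        assert params.strain_gain == 0.0
        assert params.frontal_path.a == 0.0 and params.frontal_path.b == 0.0
        m = ds.frontal
        rec = biarticular_position(m.angles_true, m.strain.single(), params)
        sb = socket_ball_position(m.angles_true, params.L, params.p0)
        np.testing.assert_allclose(rec, sb, atol=1e-12)

    def test_insufficient_samples_rejected(self, clean_shoulder):
        ds, _ = clean_shoulder
        cal = ds.frontal.calibration()
        short = CalibrationMovement(
            angles=ArmAngles(
                t=cal.angles.t[:5], theta_deg=cal.angles.theta_deg[:5],
                psi_deg=cal.angles.psi_deg[:5], rate_hz=cal.angles.rate_hz,
            ),
            strain=cal.strain[:5], gold=cal.gold[:5],
        )
        with pytest.raises(ValueError, match="insufficient calibration data"):
            identify_parameters(short, ds.sagittal.calibration())

    def test_scale_equivariance(self, clean_shoulder):
        ds, _ = clean_shoulder
        lam = 2.5
        base = identify_parameters(ds.frontal.calibration(), ds.sagittal.calibration())
        scaled = identify_parameters(
            *[
                CalibrationMovement(angles=c.angles, strain=c.strain, gold=lam * c.gold)
                for c in (ds.frontal.calibration(), ds.sagittal.calibration())
            ]
        )
        assert scaled.L == pytest.approx(lam * base.L, rel=1e-6)
        np.testing.assert_allclose(scaled.p0, lam * base.p0, rtol=1e-5, atol=1e-9)
        assert scaled.frontal_path.a == pytest.approx(lam * base.frontal_path.a, rel=1e-4)


class TestErrorOrdering:
    """The socket-ball error grows with abduction; the identified bi-articular
    model stays at the sensor-noise scale — the headline model comparison."""

    def test_socket_ball_error_strictly_increasing_in_abduction(self, clean_shoulder):
        ds, sc = clean_shoulder
        m = ds.frontal
        sb = socket_ball_position(m.angles_true, sc.L, sc.p0)
        err = np.linalg.norm(sb - m.gold, axis=1)
        levels = np.arange(20.0, 150.1, 10.0)
        idx = [np.argmin(np.abs(m.angles_true.psi_deg - lv)) for lv in levels]
        level_err = err[idx]
        assert np.all(np.diff(level_err) > 0)
        assert err.max() == pytest.approx(ds.true_params.frontal_path.chord_length(), abs=1e-9)

    def test_biarticular_beats_socket_ball_at_high_abduction(
        self, clean_shoulder, noisy_gold_shoulder
    ):
        noisy, sc = noisy_gold_shoulder
        clean, _ = clean_shoulder
        params = identify_parameters(
            noisy.frontal.calibration(), noisy.sagittal.calibration()
        )
        m = clean.frontal  # evaluate against the exact trajectory
        bi = biarticular_position(m.angles_true, m.strain.single(), params)
        sb = socket_ball_position(m.angles_true, sc.L, sc.p0)
        e_bi = np.linalg.norm(bi - m.gold, axis=1)
        e_sb = np.linalg.norm(sb - m.gold, axis=1)
        hi = m.angles_true.psi_deg >= 80.0
        assert np.all(e_bi[hi] < e_sb[hi])
        # reconstruction error bounded by twice the injected noise scale
        assert e_bi.max() <= 2 * sc.noise.gold_m


class TestTrunkRemoval:
    def test_identity_frame_passthrough(self):
        n = 10
        q = _stream(Rotation.identity(n))
        p = np.random.default_rng(4).normal(size=(n, 3))
        np.testing.assert_allclose(remove_trunk_motion(p, q, np.zeros(3)), p)

    def test_round_trip_through_known_rotation(self):
        rng = np.random.default_rng(5)
        n = 50
        rot = Rotation.from_rotvec(rng.normal(size=(n, 3)) * 0.2)
        q = _stream(rot)
        p_local = rng.normal(size=(n, 3))
        p_sternum = rng.normal(size=(n, 3))
        p_world = rot.apply(p_local) + p_sternum
        np.testing.assert_allclose(
            remove_trunk_motion(p_world, q, p_sternum), p_local, atol=1e-12
        )

    def test_sternum_position_maps_to_origin(self):
        n = 8
        rng = np.random.default_rng(6)
        rot = Rotation.from_rotvec(rng.normal(size=(n, 3)))
        p_st = rng.normal(size=(n, 3))
        out = remove_trunk_motion(p_st, _stream(rot), p_st)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        q = _stream(Rotation.identity(5))
        with pytest.raises(ValueError, match="mismatch"):
            remove_trunk_motion(np.zeros((6, 3)), q, np.zeros(3))


class TestReachClassification:
    @pytest.mark.parametrize(
        "kind,label,emg,scap",
        [
            ("physiological", "physiological", True, False),
            ("compensatory", "compensatory", False, True),
        ],
    )
    def test_active_patterns(self, kind, label, emg, scap):
        angles, env, strain = synth.gen_reach(kind, seed=2)
        out = classify_reach(env, strain, angles)
        assert len(out) == 1
        epoch = out[0]
        assert epoch.label == label
        assert epoch.emg_active is emg
        assert epoch.scapula_active is scap
        assert epoch.elevation_detected

    def test_flat_everything_is_inactive(self):
        angles, env, strain = synth.gen_reach("inactive", seed=2)
        out = classify_reach(env, strain, angles)
        assert len(out) == 1
        assert out[0].label == "inactive"
        assert not out[0].elevation_detected

    def test_emg_wins_when_both_channels_active(self):
        # deltoid-driven elevation with coexisting scapulohumeral rhythm
        angles, env, _ = synth.gen_reach("physiological", seed=3)
        _, _, strain = synth.gen_reach("compensatory", seed=3)
        out = classify_reach(env, strain, angles)
        assert out[0].label == "physiological"
        assert out[0].scapula_active

    def test_threshold_config_respected(self):
        angles, env, strain = synth.gen_reach("physiological", seed=4)
        cfg = ReachConfig(min_elevation_deg=120.0)  # unreachably high
        out = classify_reach(env, strain, angles, cfg)
        assert out[0].label == "inactive" and not out[0].elevation_detected
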