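import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinedmd.fingerprints import (
    DEFAULT_CONFIG,
    FAMILY_SIZES,
    FamilyConfig,
    autocorrelation,
    compute_autocorr_fwhm,
    compute_avg_joint_velocity,
    compute_duty_cycle,
    compute_extremity_velocity_stats,
    compute_hip_orbit_area,
    compute_joint_correlations,
    compute_logistic_scale,
    compute_segment_accel_stats,
    compute_workspace_volume,
    detect_motion,
    extract_fingerprints,
    feature_names,
    fit_logistic_scale,
    fwhm_of_autocorr,
    kruskal_wallis_screen,
)
from kinedmd.recording import DerivedStreams, differentiate
from kinedmd.skeleton import DEFAULT_SKELETON

from conftest import blank_recording


def _derived_from_velocity(velocity_66: np.ndarray) -> DerivedStreams:
    n = len(velocity_66)
    return DerivedStreams(
        joint_angular_velocity=velocity_66,
        segment_linear_velocity=np.zeros((n, 69)),
        segment_linear_acceleration=np.zeros((n, 69)),
        sample_rate=60.0,
        skeleton=DEFAULT_SKELETON,
    )


class TestWorkspaceVolume:
    def test_single_voxel_recording_gives_single_voxel_volume(self):
        rec = blank_recording(100)  # everything at the pelvis-frame origin
        full, upper, lower = compute_workspace_volume(rec)
        assert full == 8.0 and upper == 8.0 and lower == 8.0

    def test_two_voxels_give_16(self):
        rec = blank_recording(100)
        sl = DEFAULT_SKELETON.segment_slice("RightHand")
        rec.segment_positions[::2, sl.start] = 0.05  # voxel 2 on x
        full, _, _ = compute_workspace_volume(rec)
        assert full == 16.0

    def test_full_body_at_most_sum_of_parts(self, healthy_recording):
        full, upper, lower = compute_workspace_volume(healthy_recording)
        assert full <= upper + lower

    def test_invariant_to_rigid_whole_body_translation(self, healthy_recording):
        rec = healthy_recording
        before = compute_workspace_volume(rec)
        shifted = blank_recording(rec.n_frames)
        wander = np.cumsum(
            np.random.default_rng(0).normal(0, 0.01, (rec.n_frames, 3)), axis=0
        )
        shifted.joint_angles = rec.joint_angles
        shifted.segment_positions = rec.segment_positions + np.tile(wander, 23)
        np.testing.assert_allclose(compute_workspace_volume(shifted), before)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_workspace_volume(blank_recording(0))


class TestHipOrbitArea:
    def test_stationary_hip_occupies_one_cell_per_plane(self):
        rec = blank_recording(50)
        np.testing.assert_allclose(compute_hip_orbit_area(rec), [4.0, 4.0, 4.0])

    def test_circular_orbit_matches_geometric_cell_oracle(self):
        # ~6 cm radius, offset from the lattice so the ring is never tangent
        # to a 2 cm cell boundary (tangency makes cell counts ill-defined)
        r = 0.057
        rec = blank_recording(200_000)
        theta = np.linspace(0, 2 * np.pi, rec.n_frames, endpoint=False)
        sl = DEFAULT_SKELETON.segment_slice("RightUpperLeg")
        rec.segment_positions[:, sl.start] = r * np.cos(theta)  # x
        rec.segment_positions[:, sl.start + 2] = r * np.sin(theta)  # z
        sagittal = compute_hip_orbit_area(rec)[0]

        # oracle: count 2 cm cells whose [min, max] origin distance straddles r
        edge = 0.02
        expected = 0
        for i in range(-5, 5):
            for j in range(-5, 5):
                xs = np.array([i * edge, (i + 1) * edge])
                zs = np.array([j * edge, (j + 1) * edge])
                cx = np.clip(0.0, xs[0], xs[1])
                cz = np.clip(0.0, zs[0], zs[1])
                dmin = np.hypot(cx, cz)
                corners = [np.hypot(x, z) for x in xs for z in zs]
                if dmin < r < max(corners):
                    expected += 1
        assert sagittal == expected * 4.0

    def test_doubling_radius_never_shrinks_any_plane(self):
        areas = []
        for r in (0.03, 0.06):
            rec = blank_recording(5000)
            theta = np.linspace(0, 2 * np.pi, rec.n_frames, endpoint=False)
            sl = DEFAULT_SKELETON.segment_slice("RightUpperLeg")
            rec.segment_positions[:, sl.start] = r * np.cos(theta)
            rec.segment_positions[:, sl.start + 2] = r * np.sin(theta)
            areas.append(compute_hip_orbit_area(rec))
        assert np.all(areas[1] >= areas[0])


class TestExtremityVelocity:
    def test_stationary_extremities_are_zero(self):
        d = differentiate(blank_recording(100))
        np.testing.assert_allclose(compute_extremity_velocity_stats(d), 0.0)

    def test_constant_345_velocity_gives_half_meter_speed(self):
        rec = blank_recording(100)
        sl = DEFAULT_SKELETON.segment_slice("RightHand")
        t = rec.times
        rec.segment_positions[:, sl.start] = 0.3 * t
        rec.segment_positions[:, sl.start + 1] = 0.4 * t
        out = compute_extremity_velocity_stats(differentiate(rec))
        assert out[0] == pytest.approx(0.5, abs=1e-9)  # RightHand mean speed
        assert out[1] == pytest.approx(0.0, abs=1e-12)  # variance
        assert len(out) == 8


class TestAvgJointVelocity:
    def test_constant_angles_give_zero(self):
        out = compute_avg_joint_velocity(differentiate(blank_recording(100)))
        np.testing.assert_allclose(out, 0.0)
        assert len(out) == 9

    def test_ramp_recovers_slope(self):
        rec = blank_recording(200)
        ch = DEFAULT_SKELETON.joint_channel("jRightHip", "Z")
        rec.joint_angles[:, ch] = 30.0 * rec.times  # 30 deg/s
        out = compute_avg_joint_velocity(differentiate(rec))
        assert out[0] == pytest.approx(30.0, rel=1e-6)


class TestAutocorrFwhm:
    def test_sinusoid_period_three_gives_one_second(self):
        rec = blank_recording(2400)  # 40 s
        ch = DEFAULT_SKELETON.joint_channel("jRightHip", "Z")
        rec.joint_angles[:, ch] = 20 * np.sin(2 * np.pi * rec.times / 3.0)
        out = compute_autocorr_fwhm(differentiate(rec))
        assert out[0] == pytest.approx(1.0, abs=1 / 60)

    def test_white_noise_decorrelates_within_two_samples(self):
        rng = np.random.default_rng(2)
        r = autocorrelation(rng.normal(size=5000), 600)
        assert fwhm_of_autocorr(r, 60.0, 20.0) <= 2 / 60 + 1e-9

    def test_constant_channel_returns_cap(self):
        out = compute_autocorr_fwhm(differentiate(blank_recording(2400)))
        np.testing.assert_allclose(out, 20.0)
        assert len(out) == 17

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="maximum autocorrelation lag"):
            compute_autocorr_fwhm(differentiate(blank_recording(600)))


class TestLogisticScale:
    def test_recovers_known_scale(self):
        samples = stats.logistic.rvs(
            loc=0.0, scale=2.0, size=100_000, random_state=11
        )
        assert 1.9 <= fit_logistic_scale(samples) <= 2.1

    def test_constant_channel_returns_zero(self):
        out = compute_logistic_scale(differentiate(blank_recording(1200)))
        np.testing.assert_allclose(out, 0.0)
        assert len(out) == 8


class TestJointCorrelations:
    def test_self_negation_and_independence(self):
        n = 10_000
        rng = np.random.default_rng(3)
        vel = np.zeros((n, 66))
        a = DEFAULT_SKELETON.joint_channel("jL5S1", "Z")
        b = DEFAULT_SKELETON.joint_channel("jL4L3", "Z")
        c = DEFAULT_SKELETON.joint_channel("jL1T12", "Z")
        vel[:, a] = rng.normal(size=n)
        vel[:, b] = -vel[:, a]
        vel[:, c] = rng.normal(size=n)
        config = FamilyConfig(
            correlation_pairs=(
                (("jL5S1", "Z"), ("jL5S1", "Z")),
                (("jL5S1", "Z"), ("jL4L3", "Z")),
                (("jL5S1", "Z"), ("jL1T12", "Z")),
            )
        )
        r_self, r_neg, r_ind = compute_joint_correlations(
            _derived_from_velocity(vel), config
        )
        assert r_self == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)
        assert abs(r_ind) < 0.05

    def test_default_pairs_bounded(self, healthy_recording):
        out = compute_joint_correlations(differentiate(healthy_recording))
        assert len(out) == 15
        assert np.all((-1.0 <= out) & (out <= 1.0))


class TestMotionDetection:
    def test_all_zero_channel_gives_all_false(self):
        assert not detect_motion(np.zeros(500)).any()

    def test_two_level_signal_recovers_active_fraction(self):
        rng = np.random.default_rng(4)
        n = 10_000
        signal = rng.normal(0.0, 0.01, n)
        signal[: int(0.3 * n)] = 10.0 + rng.normal(0.0, 0.1, int(0.3 * n))
        frac = detect_motion(signal).mean()
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100 samples"):
            detect_motion(np.zeros(50))


class TestDutyCycle:
    def test_frozen_joints_give_zero(self):
        out = compute_duty_cycle(_derived_from_velocity(np.zeros((500, 66))))
        np.testing.assert_allclose(out, 0.0)
        assert len(out) == 15

    def test_single_axis_motion_detected_through_disjunction(self):
        rng = np.random.default_rng(5)
        n = 5000
        vel = np.zeros((n, 66))
        ch = DEFAULT_SKELETON.joint_channel("jRightKnee", "Z")
        channel = rng.normal(0.0, 0.01, n)
        active = int(0.4 * n)
        channel[:active] = 50.0 + rng.normal(0.0, 1.0, active)
        vel[:, ch] = channel
        out = compute_duty_cycle(_derived_from_velocity(vel))
        knee = DEFAULT_CONFIG.dutycycle_joints.index("jRightKnee")
        assert out[knee] == pytest.approx(0.40, abs=0.02)
        assert np.all((0.0 <= out) & (out <= 1.0))


class TestSegmentAcceleration:
    def test_constant_velocity_gives_zero(self):
        rec = blank_recording(200)
        sl = DEFAULT_SKELETON.segment_slice("RightHand")
        rec.segment_positions[:, sl.start] = 0.2 * rec.times
        out = compute_segment_accel_stats(differentiate(rec))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)
        assert len(out) == 9

    def test_sinusoid_mean_acceleration_magnitude(self):
        # |a| = A (2 pi f)^2 |sin|, and the mean of |sin| is 2/pi
        f, A = 1.0, 0.05
        rec = blank_recording(600)
        sl = DEFAULT_SKELETON.segment_slice("RightHand")
        rec.segment_positions[:, sl.start] = A * np.sin(2 * np.pi * f * rec.times)
        out = compute_segment_accel_stats(differentiate(rec))
        expected = (2 / np.pi) * A * (2 * np.pi * f) ** 2
        assert out[0] == pytest.approx(expected, rel=0.03)


class TestExtraction:
    def test_87_finite_features_with_table_family_sizes(self, healthy_recording):
        fp = extract_fingerprints(healthy_recording)
        assert len(fp) == 87
        assert np.isfinite(fp.to_numpy()).all()
        config = DEFAULT_CONFIG
        sizes = {
            "workspace_volume": 3,
            "hip_orbit_area": 3,
            "extremity_velocity": 2 * len(config.extremities),
            "avg_joint_velocity": len(config.avg_velocity_channels),
            "autocorr_fwhm": len(config.fwhm_channels),
            "logistic_scale": len(config.logistic_channels),
            "joint_correlations": len(config.correlation_pairs),
            "duty_cycle": len(config.dutycycle_joints),
            "segment_acceleration": len(config.accel_entries),
        }
        assert sizes == FAMILY_SIZES
        assert sum(sizes.values()) == 87
        assert len(feature_names(config)) == 87

    def test_extraction_is_deterministic(self, healthy_recording):
        a = extract_fingerprints(healthy_recording)
        b = extract_fingerprints(healthy_recording)
        pd.testing.assert_series_equal(a, b)


class TestKruskalWallis:
    def test_identical_groups_give_null_result(self):
        features = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = np.array(["A"] * 3 + ["B"] * 3)
        out = kruskal_wallis_screen(features, labels)
        assert out.loc["f", "H"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["f", "p"] == pytest.approx(1.0)

    def test_fully_separated_groups_are_significant(self):
        features = pd.DataFrame({"f": list(range(10)) + list(range(100, 110))})
        labels = np.array(["A"] * 10 + ["B"] * 10)
        out = kruskal_wallis_screen(features, labels)
        assert out.loc["f", "p"] < 0.001

    def test_matches_hand_computed_tied_rank_oracle(self):
        # A = [1, 2, 2], B = [3, 4, 4]; ranks 1, 2.5, 2.5, 4, 5.5, 5.5
        # H = (12/42)(36/3 + 225/3) - 21 = 27/7; tie correction
        # C = 1 - 12/210 = 33/35 gives H* = (27/7)/(33/35) = 45/11
        features = pd.DataFrame({"f": [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]})
        labels = np.array(["A"] * 3 + ["B"] * 3)
        out = kruskal_wallis_screen(features, labels)
        assert out.loc["f", "H"] == pytest.approx(45 / 11, abs=1e-9)
        assert out.loc["f", "df"] == 1
        assert out.loc["f", "median_A"] == 2.0
        assert out.loc["f", "median_B"] == 4.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis_screen(
                pd.DataFrame({"f": [1.0, 2.0]}), np.array(["A", "A"])
            )
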