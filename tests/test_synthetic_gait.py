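import numpy as np
import pytest

from gaitkin.kinematics import CHANNELS, compute_angle_series
from gaitkin.pose_benchmark import pa_mpjpe_frame
from gaitkin.synthetic_gait import (
    CohortConfig,
    GaitTemplateParams,
    SkeletonGeometry,
    angle_template,
    apply_pathology,
    forward_kinematics,
    generate_benchmark_pair,
    generate_cohort,
)
from conftest import random_template


def _rom(values):
    return values.max(axis=1) - values.min(axis=1)


class TestAngleTemplate:
    def test_constant_template(self):
        p = GaitTemplateParams(hip_mean=10.0, hip_amp=0.0,
                               knee_bump1_amp=0.0, knee_bump2_amp=0.0)
        s = angle_template(p, np.linspace(0, 1, 50))
        assert np.allclose(s.channel("LHip"), 10.0)
        assert np.allclose(s.channel("RHip"), 10.0)
        assert np.allclose(s.channel("LKnee"), 0.0)
        assert np.allclose(s.channel("RKnee"), 0.0)

    def test_phase_offset_symmetry(self, default_params):
        s = angle_template(default_params, [0.0, 0.5])
        # right channel at s=0 equals left channel at s=0.5 (offset 0.5)
        assert s.channel("RHip")[0] == pytest.approx(s.channel("LHip")[1], abs=1e-12)
        assert s.channel("RKnee")[0] == pytest.approx(s.channel("LKnee")[1], abs=1e-12)

    def test_knee_rom_matches_dense_grid_bump_sum(self, default_params):
        # independent brute-force evaluation of the two-bump formula
        p = default_params
        s_dense = np.linspace(0, 1, 20001)

        def bump(s, amp, c, w):
            d = s - c
            d -= np.round(d)
            return amp * np.exp(-0.5 * (d / w) ** 2)

        knee = (bump(s_dense, p.knee_bump1_amp, p.knee_bump1_center, p.knee_bump1_width)
                + bump(s_dense, p.knee_bump2_amp, p.knee_bump2_center, p.knee_bump2_width))
        expected_rom = knee.max() - knee.min()
        series = angle_template(p, s_dense)
        got = series.channel("LKnee")
        assert got.max() - got.min() == pytest.approx(expected_rom, abs=1e-9)

    def test_empty_phases_rejected(self, default_params):
        with pytest.raises(ValueError):
            angle_template(default_params, [])

    def test_decreasing_phases_rejected(self, default_params):
        with pytest.raises(ValueError):
            angle_template(default_params, [0.5, 0.2])


class TestApplyPathology:
    def test_identity(self, default_params):
        s = angle_template(default_params, np.linspace(0, 1, 80))
        out = apply_pathology(s, 1.0, timing_jitter_sd=0.0)
        np.testing.assert_array_equal(out.values, s.values)

    def test_affine_scaling_about_minimum(self, default_params):
        s = angle_template(default_params, np.linspace(0, 1, 80))
        out = apply_pathology(s, 0.5)
        np.testing.assert_allclose(_rom(out.values), 0.5 * _rom(s.values),
                                   atol=1e-12)
        np.testing.assert_allclose(out.values.min(axis=1), s.values.min(axis=1),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rom_scaling_exact_on_random_templates(self, seed):
        rng = np.random.default_rng(seed)
        s = angle_template(random_template(rng), np.linspace(0, 1, 120))
        out = apply_pathology(s, 0.44)
        np.testing.assert_allclose(_rom(out.values), 0.44 * _rom(s.values),
                                   atol=1e-9)

    def test_rom_exact_even_with_timing_jitter(self, default_params, rng):
        s = angle_template(default_params, np.linspace(0, 1, 150))
        out = apply_pathology(s, 0.7, timing_jitter_sd=0.03, rng=rng)
        np.testing.assert_allclose(_rom(out.values), 0.7 * _rom(s.values),
                                   atol=1e-9)

    def test_invalid_scale_rejected(self, default_params):
        s = angle_template(default_params, np.linspace(0, 1, 10))
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                apply_pathology(s, bad)


class TestForwardKinematics:
    def test_straight_leg_collinear(self, geom):
        from gaitkin.kinematics import JointAngleSeries

        s = JointAngleSeries(np.zeros((4, 5)))
        traj = forward_kinematics(s, geom)
        for side in "LR":
            for i in range(5):
                pts = [traj.xyz[i, traj.index_of(n)]
                       for n in ("Root", f"IAS_{side}", f"FLE_{side}", f"FAL_{side}")]
                # Root->IAS, IAS->FLE, FLE->FAL all parallel
                v0 = pts[1] - pts[0]
                for a, b in ((pts[2] - pts[1], v0), (pts[3] - pts[2], v0)):
                    cross = np.cross(a / np.linalg.norm(a), b / np.linalg.norm(b))
                    assert np.linalg.norm(cross) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_recovers_angles(self, seed, geom):
        rng = np.random.default_rng(seed)
        s = angle_template(random_template(rng), np.linspace(0, 1, 90))
        rec = compute_angle_series(forward_kinematics(s, geom))
        np.testing.assert_allclose(rec.values, s.values, atol=1e-6)

    def test_mirror_consistency(self, default_params, geom):
        s = angle_template(default_params, np.linspace(0, 1, 70))
        fwd = compute_angle_series(forward_kinematics(s, geom, direction=+1))
        rev = compute_angle_series(forward_kinematics(s, geom, direction=-1))
        swapped = rev.values[[CHANNELS.index(c)
                              for c in ("RHip", "LHip", "RKnee", "LKnee")]]
        np.testing.assert_allclose(swapped, fwd.values, atol=1e-6)

    def test_nonfinite_angles_rejected(self, geom):
        from gaitkin.kinematics import JointAngleSeries

        s = JointAngleSeries(np.full((4, 5), 10.0))
        s.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            forward_kinematics(s, geom)


class TestGenerateCohort:
    def test_counting_and_no_reversal(self):
        cfg = CohortConfig(n_per_class=3, reversed_fraction=0.0, seed=7,
                           frame_count_range=(40, 60))
        trials = generate_cohort(cfg)
        assert len(trials) == 6
        assert sum(t.truth.reversed for t in trials) == 0
        assert sum(t.label == "SCI" for t in trials) == 3

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(n_per_class=4, seed=11, frame_count_range=(40, 80))
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.trajectory.xyz, tb.trajectory.xyz)
            assert ta.truth.reversed == tb.truth.reversed

    def test_reversed_share_within_binomial_interval(self):
        cfg = CohortConfig(n_per_class=150, reversed_fraction=0.3, seed=3,
                           frame_count_range=(10, 12), keypoint_noise_sd=0.0)
        trials = generate_cohort(cfg)
        n = len(trials)
        share = sum(t.truth.reversed for t in trials) / n
        half = 2.576 * np.sqrt(0.3 * 0.7 / n)  # 99% normal-approx interval
        assert abs(share - 0.3) <= half

    def test_sci_trials_have_reduced_rom_in_truth(self):
        cfg = CohortConfig(n_per_class=2, rom_scale_sci=0.5, seed=5,
                           frame_count_range=(80, 100), timing_jitter_sd=0.0)
        trials = generate_cohort(cfg)
        healthy = next(t for t in trials if t.label == "Healthy")
        sci = next(t for t in trials if t.label == "SCI")
        rom_h = _rom(healthy.truth.clean_angles.values)
        rom_s = _rom(sci.truth.clean_angles.values)
        np.testing.assert_allclose(rom_s, 0.5 * rom_h, rtol=0.02)


class TestBenchmarkPair:
    def test_identity_transform_exact(self):
        gt, pred = generate_benchmark_pair(5, noise_sd=0.0)
        np.testing.assert_array_equal(gt.xyz, pred.xyz)

    def test_similarity_transform_removed_by_alignment(self, rng):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=4).as_matrix()
        gt, pred = generate_benchmark_pair(4, rotation=R,
                                           translation=np.array([10., -5., 3.]),
                                           scale=1.7, noise_sd=0.0, rng=rng)
        for i in range(4):
            assert pa_mpjpe_frame(pred.xyz[i], gt.xyz[i]) < 1e-9

    def test_error_grows_with_noise(self):
        means = []
        for sd in (1.0, 5.0, 20.0):
            errs = []
            for rep in range(10):
                rng = np.random.default_rng(100 + rep)
                gt, pred = generate_benchmark_pair(3, noise_sd=sd, rng=rng)
                errs.extend(pa_mpjpe_frame(pred.xyz[i], gt.xyz[i])
                            for i in range(3))
            means.append(np.mean(errs))
        assert means[0] < means[1] < means[2]

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            generate_benchmark_pair(3, scale=0.0)
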