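import numpy as np
import pytest

from gaitkin.cycle_qc import (
    build_subsets,
    classify_clusters,
    cluster_cycles,
    detect_reversed_clusters,
    flip_trial,
    select_typical_cluster,
    subset_cycles,
)
from gaitkin.io import reference_signature
from conftest import make_cycle


def _gait_cycles(n, rng, noise=1.0, swap=False, offset=0.0, prefix="t"):
    base = reference_signature()
    if swap:
        base = base[[1, 0, 3, 2]]
    out = []
    for i in range(n):
        m = np.clip(base + offset + rng.normal(0, noise, base.shape), 0, 180)
        out.append(make_cycle(m, trial_id=f"{prefix}{i}"))
    return out


class TestClusterCycles:
    def test_k1_centroid_is_global_mean(self, rng):
        cycles = _gait_cycles(6, rng)
        model = cluster_cycles(cycles, k=1, seed=0)
        expected = np.mean([c.matrix for c in cycles], axis=0)
        np.testing.assert_allclose(model.centroids[0], expected, atol=1e-8)

    def test_two_separated_groups_recovered(self, rng):
        a = _gait_cycles(8, rng, noise=0.5, prefix="a")
        b = _gait_cycles(8, rng, noise=0.5, offset=40.0, prefix="b")
        model = cluster_cycles(a + b, k=2, seed=0)
        la = {model.assignments[c.trial_id] for c in a}
        lb = {model.assignments[c.trial_id] for c in b}
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_duplicated_cycles_zero_inertia(self, rng):
        base = _gait_cycles(1, rng)[0]
        cycles = [make_cycle(base.matrix, trial_id=f"d{i}") for i in range(5)]
        model = cluster_cycles(cycles, k=1, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-6)

    def test_fewer_cycles_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_cycles(_gait_cycles(3, rng), k=5)

    def test_deterministic_under_seed(self, rng):
        cycles = _gait_cycles(12, rng)
        m1 = cluster_cycles(cycles, k=3, seed=42)
        m2 = cluster_cycles(cycles, k=3, seed=42)
        assert m1.assignments == m2.assignments
        np.testing.assert_array_equal(m1.centroids, m2.centroids)


class TestDetectReversed:
    def test_exact_mirror_detected(self, rng):
        ref = _gait_cycles(5, rng, noise=0.5, prefix="r")
        mir = _gait_cycles(5, rng, noise=0.5, swap=True, prefix="m")
        model = cluster_cycles(ref + mir, k=2, seed=0)
        ref_cluster = model.assignments["r0"]
        detected = detect_reversed_clusters(model, ref_cluster)
        assert detected == {model.assignments["m0"]}

    def test_unswapped_copy_not_detected(self, rng):
        a = _gait_cycles(5, rng, noise=0.5, prefix="a")
        b = _gait_cycles(5, rng, noise=0.5, prefix="b")
        model = cluster_cycles(a + b, k=2, seed=0)
        assert detect_reversed_clusters(model, 0) == set()
        assert detect_reversed_clusters(model, 1) == set()

    def test_invalid_reference_rejected(self, rng):
        model = cluster_cycles(_gait_cycles(4, rng), k=2, seed=0)
        with pytest.raises(ValueError):
            detect_reversed_clusters(model, 9)

    def test_mirror_clusters_found_across_seeded_cohorts(self):
        # 30% mirrored trials: the mirror-dominated clusters end up in the
        # reversed set (majority orientation fixes a mirrored reference)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            normal = _gait_cycles(14, rng, noise=2.0, prefix="n")
            mirrored = _gait_cycles(6, rng, noise=2.0, swap=True, prefix="m")
            model = cluster_cycles(normal + mirrored, k=5, seed=seed)
            ref = select_typical_cluster(model)
            _, detected, _ = classify_clusters(model, ref)
            mirror_clusters = {model.assignments[c.trial_id] for c in mirrored}
            hits += mirror_clusters <= detected
        assert hits >= 0.95 * n_seeds


class TestFlipTrial:
    def test_involution(self, rng):
        cyc = _gait_cycles(1, rng)[0]
        np.testing.assert_array_equal(flip_trial(flip_trial(cyc)).matrix,
                                      cyc.matrix)

    def test_symmetric_cycle_unchanged(self):
        m = np.tile(np.linspace(5, 50, 101), (4, 1))  # L == R
        cyc = make_cycle(m)
        np.testing.assert_array_equal(flip_trial(cyc).matrix, m)

    def test_swaps_left_right_channels(self, rng):
        cyc = _gait_cycles(1, rng)[0]
        out = flip_trial(cyc)
        np.testing.assert_array_equal(out.channel("LHip"), cyc.channel("RHip"))
        np.testing.assert_array_equal(out.channel("LKnee"), cyc.channel("RKnee"))

    def test_time_reverse_mode(self, rng):
        cyc = _gait_cycles(1, rng)[0]
        out = flip_trial(cyc, mode="time_reverse")
        np.testing.assert_array_equal(out.channel("LHip"),
                                      cyc.channel("RHip")[::-1])

    def test_flipped_mirror_matches_unmirrored_twin(self, rng):
        base = reference_signature()
        noise = rng.normal(0, 1.0, base.shape)
        twin = make_cycle(np.clip(base + noise, 0, 180))
        mirrored = make_cycle(np.clip(base[[1, 0, 3, 2]] + noise[[1, 0, 3, 2]],
                                      0, 180))
        np.testing.assert_allclose(flip_trial(mirrored).matrix, twin.matrix,
                                   atol=1e-12)


class TestBuildSubsets:
    def test_no_reversed_clusters_subsets_equal(self, rng):
        model = cluster_cycles(_gait_cycles(6, rng), k=2, seed=0)
        s1, s2 = build_subsets(model, {0, 1}, set())
        assert s1.kept_trials == s2.kept_trials
        assert s2.flipped_trials == set()

    def test_counting(self, rng):
        normal = _gait_cycles(10, rng, noise=0.5, prefix="n")
        mirrored = _gait_cycles(4, rng, noise=0.5, swap=True, prefix="m")
        model = cluster_cycles(normal + mirrored, k=2, seed=0)
        typ = {model.assignments["n0"]}
        rev = {model.assignments["m0"]}
        s1, s2 = build_subsets(model, typ, rev)
        assert len(s1.kept_trials) == 10
        assert len(s2.kept_trials) == 14
        assert len(s2.flipped_trials) == 4

    def test_overlapping_sets_rejected(self, rng):
        model = cluster_cycles(_gait_cycles(4, rng), k=2, seed=0)
        with pytest.raises(ValueError):
            build_subsets(model, {0}, {0})

    def test_flip_correction_restores_mirrored_trials(self, rng):
        normal = _gait_cycles(10, rng, noise=1.0, prefix="n")
        mirrored = _gait_cycles(5, rng, noise=1.0, swap=True, prefix="m")
        model = cluster_cycles(normal + mirrored, k=2, seed=0)
        ref = select_typical_cluster(model)
        typ, rev, _ = classify_clusters(model, ref)
        _, s2 = build_subsets(model, typ, rev)
        assert s2.flipped_trials == {c.trial_id for c in mirrored}
        corrected = subset_cycles(model, s2)
        base = reference_signature()
        for cyc in corrected:
            # all corrected cycles now resemble the unmirrored signature
            assert np.abs(cyc.matrix - base).mean() < 4.0


class TestSelectTypical:
    def test_prefers_gait_shaped_over_flat_noise(self, rng):
        flat = [make_cycle(np.clip(20 + rng.normal(0, 0.5, (4, 101)), 0, 180),
                           trial_id=f"f{i}") for i in range(6)]
        gait = _gait_cycles(6, rng, noise=0.5, prefix="g")
        model = cluster_cycles(flat + gait, k=2, seed=0)
        chosen = select_typical_cluster(model)
        assert chosen == model.assignments["g0"]

    def test_single_cluster(self, rng):
        model = cluster_cycles(_gait_cycles(4, rng), k=1, seed=0)
        assert select_typical_cluster(model) == 0

    def test_override_returned_verbatim(self, rng):
        model = cluster_cycles(_gait_cycles(6, rng), k=3, seed=0)
        assert select_typical_cluster(model, override=2) == 2
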