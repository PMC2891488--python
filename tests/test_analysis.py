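"""Structural metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crowdfold.analysis import (contact_map, eligibility_mask, fixation_time,
                                maxsub_fraction, native_like_time,
                                radius_of_gyration, relative_rg,
                                select_foldable, smooth_trace, summarize,
                                superpose, tm_d0, tm_score)
from crowdfold.io import make_fixture

from helpers_oracles import (fixation_bruteforce, maxsub_subset_oracle,
                             superpose_grid_oracle, tm_grid_oracle)


def rigid(conf, seed=0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return conf @ R.T + t


@pytest.fixture(scope="module")
def helix20():
    return make_fixture("ideal_helix", length=20).ca


@pytest.fixture(scope="module")
def coil8():
    return make_fixture("random_coil", length=8, seed=3).ca


class TestSuperpose:
    def test_identical_structures_have_zero_rmsd(self, helix20):
        R, t, rmsd = superpose(helix20, helix20)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)

    def test_rigid_transform_recovered(self, helix20):
        B = rigid(helix20, seed=1)
        _, _, rmsd = superpose(helix20, B)
        assert rmsd == pytest.approx(0, abs=1e-6)

    def test_rotation_is_proper(self, rng):
        A = rng.normal(0, 3, (6, 3))
        B = rng.normal(0, 3, (6, 3))
        R, _, _ = superpose(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(3):
            A = rng.normal(0, 3, (6, 3))
            B = rng.normal(0, 3, (6, 3))
            _, _, rmsd = superpose(A, B)
            assert rmsd == pytest.approx(superpose_grid_oracle(A, B),
                                         abs=1e-3)

    def test_rejects_degenerate_input(self):
        line = np.stack([np.arange(5.), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTMScore:
    def test_self_score_is_one(self, helix20):
        assert tm_score(helix20, helix20) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_invariance(self, helix20):
        assert tm_score(rigid(helix20, 5), helix20) == pytest.approx(
            1.0, abs=1e-6)

    def test_d0_formula_at_L20(self):
        assert tm_d0(20) == pytest.approx(1.24 * 5 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(20) == pytest.approx(0.320, abs=5e-3)

    def test_short_chains_rejected(self):
        c = np.zeros((4, 3))
        with pytest.raises(ValueError, match="fewer than 5"):
            tm_score(c, c)

    def test_matches_dense_grid_oracle_on_toys(self, coil8):
        native = coil8
        rng = np.random.default_rng(9)
        d0 = 0.5  # clamped value for L = 8
        decoys = [
            native + rng.normal(0, 0.4, native.shape),
            native + rng.normal(0, 1.5, native.shape),
            rigid(native, 2) + rng.normal(0, 0.8, native.shape),
        ]
        for decoy in decoys:
            got = tm_score(decoy, native)
            ref = tm_grid_oracle(decoy, native, d0)
            assert got == pytest.approx(ref, abs=0.01)


class TestMaxsub:
    def test_self_fraction_is_one(self, helix20):
        assert maxsub_fraction(helix20, helix20) == 1.0

    def test_scrambled_structure_small_alignable_set(self, coil8):
        rng = np.random.default_rng(4)
        scrambled = rng.normal(0, 20, coil8.shape)
        got = maxsub_fraction(scrambled, coil8)
        oracle = maxsub_subset_oracle(scrambled, coil8, 5.0) / len(coil8)
        assert got <= oracle + 1e-12
        assert oracle <= 6 / 8  # the random cloud is mostly unalignable

    def test_agrees_with_exhaustive_subsets_on_mixed_decoy(self, coil8):
        rng = np.random.default_rng(6)
        decoy = coil8.copy()
        decoy[4:] += rng.normal(0, 12, (4, 3))  # break half the structure
        got = maxsub_fraction(decoy, coil8)
        oracle = maxsub_subset_oracle(decoy, coil8, 5.0) / len(coil8)
        assert got == pytest.approx(oracle, abs=1 / len(coil8))

    def test_monotone_in_cutoff(self, coil8, rng):
        decoy = coil8 + rng.normal(0, 2.0, coil8.shape)
        fracs = [maxsub_fraction(decoy, coil8, d_cut=d)
                 for d in (7.0, 5.0, 3.0, 1.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestRadiusOfGyration:
    def test_native_ratio_is_one(self, helix20):
        assert relative_rg(helix20, helix20) == 1.0

    def test_two_point_closed_form(self):
        conf = np.array([[0, 0, 0], [6.0, 0, 0]])
        assert radius_of_gyration(conf) == pytest.approx(3.0)

    def test_matches_direct_sum_oracle(self, rng):
        conf = rng.normal(0, 5, (30, 3))
        c = conf.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((conf - c) ** 2, axis=1)))
        assert radius_of_gyration(conf) == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_native_rejected(self):
        with pytest.raises(ValueError, match="zero radius"):
            relative_rg(np.zeros((3, 3)), np.zeros((3, 3)))


class TestFixation:
    def test_constant_trajectory_fixes_immediately(self, helix20):
        frames = np.repeat(helix20[None], 5, axis=0)
        assert fixation_time(frames) == 0

    def test_divergent_final_sample_pushes_to_last_index(self, helix20):
        frames = np.repeat(helix20[None], 5, axis=0)
        frames[-1] *= 3.0
        assert fixation_time(frames) == 4

    def test_equals_brute_force_on_random_trajectories(self, rng):
        for _ in range(3):
            frames = rng.normal(0, 4, (50, 10, 3)).cumsum(axis=0) * 0.2
            theta = 4.0
            assert fixation_time(frames, theta) == fixation_bruteforce(
                frames, theta)

    def test_superposition_free(self, helix20):
        frames = np.stack([helix20, rigid(helix20, 3)])
        assert fixation_time(frames) == 0  # internal distances identical


class TestNativeLikeTime:
    def test_all_native_gives_100(self, helix20):
        frames = np.repeat(helix20[None], 4, axis=0)
        assert native_like_time(frames, helix20) == 100.0

    def test_counting_of_mixed_pool(self, helix20, rng):
        far = rng.normal(0, 30, helix20.shape)
        frames = np.stack([helix20, helix20, helix20, far])
        assert native_like_time(frames, helix20) == pytest.approx(75.0)

    def test_no_native_like_samples(self, helix20, rng):
        frames = rng.normal(0, 30, (3,) + helix20.shape)
        assert native_like_time(frames, helix20) == 0.0


class TestContactMap:
    def test_straight_chain_contacts_only_near_diagonal(self):
        L = 20
        conf = np.stack([np.zeros(L), np.zeros(L), 3.8 * np.arange(L)], 1)
        conf[:, 0] = 0.9 * (-1) ** np.arange(L)
        cm = contact_map(conf, "C" * L)
        i, j = np.nonzero(np.triu(cm.values, k=1))
        assert np.all(j - i <= 3)   # 11 A cutoff reaches ~3 residues

    def test_same_unit_pairs_ineligible(self):
        ss = "HHHHHHCCEE"
        mask = eligibility_mask(ss)
        assert not mask[0, 5]   # same helix
        assert not mask[8, 9]   # same strand
        assert mask[0, 8]       # helix vs strand
        assert mask[6, 7]       # coil pairs always eligible
        assert not mask.diagonal().any()

    def test_strand_pairs_use_shorter_cutoff(self):
        conf = np.zeros((10, 3))
        conf[:, 2] = np.arange(10) * 3.8
        conf[5:, 0] = 9.0   # second strand 9 A away
        ss = "EEEEECEEEE"
        cm = contact_map(conf, ss)
        # 9 A exceeds the 8 A strand cutoff but not the generic 11 A
        smoothed = smooth_trace(conf)
        d = np.linalg.norm(smoothed[2] - smoothed[8])
        if 8.0 < d < 11.0:
            assert cm.values[2, 8] == 0.0

    def test_short_chain_smoothing_still_defined(self):
        conf = np.random.default_rng(0).normal(0, 3, (5, 3))
        cm = contact_map(conf, "CCCCC")
        assert cm.values.shape == (5, 5)
        assert np.allclose(cm.values, cm.values.T)

    def test_eligibility_independent_of_coordinates(self, rng):
        ss = "HHHHCCEEEE"
        a = contact_map(rng.normal(0, 5, (10, 3)), ss)
        b = contact_map(rng.normal(0, 5, (10, 3)), ss)
        assert np.array_equal(a.eligible, b.eligible)


class TestSummaries:
    def test_interpolated_quartiles(self):
        assert summarize([1, 2, 3]) == (2.0, 1.5, 2.5)

    def test_constant_collapses(self):
        assert summarize([4.0] * 10) == (4.0, 4.0, 4.0)

    def test_matches_sorted_quantile_oracle(self, rng):
        vals = rng.normal(0, 1, 500)
        med, p25, p75 = summarize(vals)
        s = np.sort(vals)

        def q(p):
            h = (len(s) - 1) * p
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert med == pytest.approx(q(0.5))
        assert p25 == pytest.approx(q(0.25))
        assert p75 == pytest.approx(q(0.75))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_select_foldable_boundary_inclusive(self):
        times = {"a": 0.0, "b": 10.0, "c": 25.0, "d": 9.9}
        assert select_foldable(times) == ["b", "c"]
        assert select_foldable({"a": 0.0, "b": 0.0}) == []
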