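import math

import numpy as np
import pytest

from codiv.config_io import PriorSpec, uniform_config
from codiv.coalsim import simulate_dataset
from codiv.hyperprior import draw_hyper
from codiv.sumstats import (
    STAT_CLASSES,
    build_summary_tensor,
    locus_stats,
    pairwise_diff_stats,
    reduce_moments,
    sd_pi_theta,
    shannon,
    watterson,
    wakeley_stats,
)

from conftest import (
    bf_cross_stats,
    bf_pi,
    bf_pi_b,
    bf_shannon,
    bf_watterson,
    bf_within_s,
    make_alignment,
    random_alignment,
)


class TestPairwiseDiffs:
    def test_single_sequence_per_population(self):
        aln = make_alignment(["AAAA"], ["AATT"])
        pi_pool, pi_1, pi_2, pi_b, pi_net = pairwise_diff_stats(aln)
        assert pi_b == 2.0
        assert math.isnan(pi_1) and math.isnan(pi_2)

    def test_two_by_two_example(self):
        aln = make_alignment(["AAAA", "AAAT"], ["TTAA", "TTAT"])
        pi_pool, pi_1, pi_2, pi_b, pi_net = pairwise_diff_stats(aln)
        assert pi_1 == 1.0 and pi_2 == 1.0
        assert pi_b == 2.5
        assert pi_net == 1.5

    def test_monomorphic_alignment_is_all_zero(self):
        aln = make_alignment(["ACGT", "ACGT"], ["ACGT", "ACGT"])
        pi_pool, pi_1, pi_2, pi_b, pi_net = pairwise_diff_stats(aln)
        assert pi_pool == pi_1 == pi_2 == pi_b == pi_net == 0.0

    def test_single_sequence_total_rejected(self):
        aln = make_alignment(["ACGT"], [])
        with pytest.raises(ValueError):
            pairwise_diff_stats(aln)


class TestWatterson:
    def test_two_sequences(self):
        aln = make_alignment(["AAAA"], ["ATTT"])
        assert watterson(aln.matrix) == 3.0  # a_1 = 1

    def test_four_sequences(self):
        # 11 segregating sites among n=4: theta_W = 11 / a_3 = 11 / (11/6) = 6
        base = "A" * 20
        variant = "C" * 11 + "A" * 9  # 11 segregating columns
        aln = make_alignment([base, base], [variant, base])
        s = (aln.matrix != aln.matrix[0]).any(axis=0).sum()
        assert s == 11
        assert watterson(aln.matrix) == pytest.approx(6.0)

    def test_no_segregating_sites(self):
        aln = make_alignment(["ACGT", "ACGT"], ["ACGT"])
        assert watterson(aln.matrix) == 0.0


class TestSdPiTheta:
    def test_zero_when_no_segregating_sites(self):
        aln = make_alignment(["ACGT", "ACGT"], [])
        assert sd_pi_theta(aln.matrix) == 0.0

    def test_matches_independent_coefficient_algebra(self):
        # independent implementation of the variance estimator of
        # (pi - theta_W) from n and S
        def oracle(n, s):
            a1 = sum(1.0 / i for i in range(1, n))
            a2 = sum(1.0 / i ** 2 for i in range(1, n))
            b1 = (n + 1) / (3.0 * (n - 1))
            b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
            c1 = b1 - 1.0 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
            e1 = c1 / a1
            e2 = c2 / (a1 ** 2 + a2)
            return math.sqrt(e1 * s + e2 * s * (s - 1))

        rng = np.random.default_rng(4)
        aln = random_alignment(rng, 2, 2, 30)
        s = int((aln.matrix != aln.matrix[0]).any(axis=0).sum())
        assert sd_pi_theta(aln.matrix) == pytest.approx(oracle(4, s), rel=1e-12)

    def test_depends_only_on_n_and_s(self):
        a = make_alignment(["AAAA", "AAAT"], ["AAAA", "AATA"])  # S=2, n=4
        b = make_alignment(["CCCC", "CCGC"], ["CCCC", "GCCC"])  # S=2, n=4
        assert sd_pi_theta(a.matrix) == sd_pi_theta(b.matrix)


class TestShannon:
    def test_two_singleton_haplotypes(self):
        aln = make_alignment(["AAAA"], ["AATT"])
        assert shannon(aln.matrix) == pytest.approx(math.log(2))

    def test_monomorphic(self):
        aln = make_alignment(["AAAA", "AAAA"], [])
        assert shannon(aln.matrix) == 0.0

    def test_four_distinct(self):
        aln = make_alignment(["AAAA", "CCCC"], ["GGGG", "TTTT"])
        assert shannon(aln.matrix) == pytest.approx(math.log(4))


class TestWakeley:
    def test_monomorphic_returns_zero(self):
        aln = make_alignment(["ACGT"] * 3, ["ACGT"] * 3)
        s1, s2, s_pool, s_xy, psi_w = wakeley_stats(aln)
        assert s1 == s2 == s_pool == s_xy == psi_w == 0.0

    def test_hand_built_alignment_matches_brute_force(self, rng):
        aln = random_alignment(rng, 3, 3, 40)
        rows = [tuple(r) for r in aln.matrix]
        s1, s2, s_pool, s_xy, psi_w = wakeley_stats(aln)
        assert s1 == pytest.approx(bf_within_s(rows[:3]), abs=1e-12)
        assert s2 == pytest.approx(bf_within_s(rows[3:]), abs=1e-12)
        assert s_pool == pytest.approx(bf_within_s(rows), abs=1e-12)
        o_sxy, o_psi = bf_cross_stats(rows[:3], rows[3:])
        assert s_xy == pytest.approx(o_sxy, abs=1e-12)
        assert psi_w == pytest.approx(o_psi, abs=1e-12)

    def test_population_label_swap_symmetry(self, rng):
        aln = random_alignment(rng, 3, 4, 30)
        swapped = type(aln)(
            np.vstack([aln.matrix[3:], aln.matrix[:3]]),
            np.r_[np.ones(4, dtype=int), np.full(3, 2, dtype=int)],
        )
        a = wakeley_stats(aln)
        b = wakeley_stats(swapped)
        assert a[2] == pytest.approx(b[2], abs=1e-12)   # s_pool
        assert a[3] == pytest.approx(b[3], abs=1e-12)   # s_XY
        assert a[4] == pytest.approx(b[4], abs=1e-12)   # psi_W
        assert a[0] == pytest.approx(b[1], abs=1e-12)   # s_1 <-> s_2
        assert a[1] == pytest.approx(b[0], abs=1e-12)

    def test_too_small_samples_are_masked(self):
        aln = make_alignment(["AAAA"], ["AATT"])
        s1, s2, s_pool, s_xy, psi_w = wakeley_stats(aln)
        assert math.isnan(s1) and math.isnan(s2) and math.isnan(s_pool)
        assert math.isnan(s_xy) and math.isnan(psi_w)


class TestBruteForceAgreement:
    def test_all_statistics_on_random_alignments(self, rng):
        # randomized cross-check of the vectorized statistics against the
        # explicit-loop reference on small alignments
        for _ in range(60):
            n1 = int(rng.integers(1, 5))
            n2 = int(rng.integers(1, 9 - n1))
            length = int(rng.integers(5, 25))
            aln = random_alignment(rng, n1, n2, length, n_states=2)
            rows = [tuple(r) for r in aln.matrix]
            rows1, rows2 = rows[:n1], rows[n1:]
            stats = locus_stats(aln, STAT_CLASSES)
            assert stats["pi.pool"] == pytest.approx(bf_pi(rows), abs=1e-12)
            assert stats["pi_b"] == pytest.approx(bf_pi_b(rows1, rows2), abs=1e-12)
            assert stats["thetaW.pool"] == pytest.approx(
                bf_watterson(rows), abs=1e-12)
            assert stats["shannon.pool"] == pytest.approx(
                bf_shannon(rows), abs=1e-12)
            for vals, key in ((rows1, "1"), (rows2, "2")):
                for name, oracle in (("pi", bf_pi), ("thetaW", bf_watterson)):
                    got = stats[f"{name}.{key}"]
                    want = oracle(vals)
                    if isinstance(want, float) and math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)
            want_s = bf_within_s(rows)
            if math.isnan(want_s):
                assert math.isnan(stats["wakeley_s.pool"])
            else:
                assert stats["wakeley_s.pool"] == pytest.approx(want_s, abs=1e-12)
            want_sxy, want_psi = bf_cross_stats(rows1, rows2)
            if math.isnan(want_sxy):
                assert math.isnan(stats["wakeley_sxy"])
            else:
                assert stats["wakeley_sxy"] == pytest.approx(want_sxy, abs=1e-12)
                assert stats["wakeley_psiW"] == pytest.approx(want_psi, abs=1e-12)

    def test_pi_net_identity_on_simulated_data(self, rng):
        config = uniform_config(3, 2, 3, 3, 200)
        h = draw_hyper(config, PriorSpec(), rng)
        ds = simulate_dataset(h, config, rng)
        for pair in ds.alignments:
            for aln in pair:
                st = locus_stats(aln, ("pi.1", "pi.2", "pi_b", "pi_net"))
                assert st["pi_net"] == pytest.approx(
                    st["pi_b"] - 0.5 * (st["pi.1"] + st["pi.2"]), abs=1e-12)


class TestTensor:
    def test_shape_for_selected_classes(self, rng):
        data = [[random_alignment(rng, 2, 2, 20) for _ in range(2)]
                for _ in range(3)]
        tensor = build_summary_tensor(data, ("pi_b",))
        assert tensor.n_pairs == 3
        assert all(b.shape == (1, 2) for b in tensor.blocks)

    def test_unknown_class_rejected(self, rng):
        data = [[random_alignment(rng, 2, 2, 20)]]
        with pytest.raises(ValueError, match="unknown"):
            build_summary_tensor(data, ("pi_b", "nope"))

    def test_single_individual_pair_masks_within_population_classes(self, rng):
        # one sequence per descendant population: within-population
        # statistics are undefined for that pair but pi_b remains defined
        data = [[random_alignment(rng, 1, 1, 30)]]
        tensor = build_summary_tensor(data, ("pi.1", "pi.2", "pi_b"))
        block = data and tensor.blocks[0]
        assert math.isnan(block[0, 0]) and math.isnan(block[1, 0])
        assert not math.isnan(block[2, 0])

    def test_identical_datasets_give_identical_tensors(self, rng):
        data = [[random_alignment(rng, 2, 2, 20)] for _ in range(2)]
        t1 = build_summary_tensor(data, ("pi_b", "shannon.pool"))
        t2 = build_summary_tensor(data, ("pi_b", "shannon.pool"))
        for b1, b2 in zip(t1.blocks, t2.blocks):
            np.testing.assert_array_equal(b1, b2)


class TestMoments:
    def test_raw_moments_of_small_series(self, rng):
        data = [[make_alignment(["A" * 10], ["A" * (10 - k) + "T" * k])
                 for k in (1, 2, 3, 4)]]
        tensor = build_summary_tensor(data, ("pi_b",))
        mv = reduce_moments(tensor, 4)
        np.testing.assert_allclose(mv.values[0, 0], [2.5, 7.5, 25.0, 88.5])

    def test_sort_permutation_by_descending_mean_pi_b(self):
        def pair(k):
            return [make_alignment(["A" * 10], ["A" * (10 - k) + "T" * k])]

        data = [pair(2), pair(5), pair(3)]
        mv = reduce_moments(build_summary_tensor(data, ("pi_b",)), 1)
        np.testing.assert_array_equal(mv.permutation, [1, 2, 0])
        np.testing.assert_allclose(mv.values[0, :, 0], [5.0, 3.0, 2.0])

    def test_single_locus_moment_is_power(self):
        data = [[make_alignment(["A" * 10], ["A" * 7 + "T" * 3])]]
        mv = reduce_moments(build_summary_tensor(data, ("pi_b",)), 4)
        np.testing.assert_allclose(mv.values[0, 0], [3.0, 9.0, 27.0, 81.0])

    def test_pair_permutation_invariance(self, rng):
        # the pi_b sort makes D_m independent of taxon-pair input order
        data = [[random_alignment(rng, 2, 2, 40) for _ in range(3)]
                for _ in range(4)]
        base = reduce_moments(
            build_summary_tensor(data, ("pi_b", "thetaW.pool")), 2).values
        for _ in range(5):
            perm = rng.permutation(4)
            shuffled = [data[i] for i in perm]
            got = reduce_moments(
                build_summary_tensor(shuffled, ("pi_b", "thetaW.pool")), 2
            ).values
            np.testing.assert_allclose(got, base, atol=1e-12)

    def test_empty_class_for_pair_rejected(self, rng):
        # a pair whose only locus cannot define pi_net must be rejected
        data = [[random_alignment(rng, 1, 1, 20)]]
        tensor = build_summary_tensor(data, ("pi_b", "pi_net"))
        with pytest.raises(ValueError, match="pair 0"):
            reduce_moments(tensor, 1)

    def test_sort_requires_pi_b(self, rng):
        data = [[random_alignment(rng, 2, 2, 20)]]
        tensor = build_summary_tensor(data, ("shannon.pool",))
        with pytest.raises(ValueError, match="pi_b"):
            reduce_moments(tensor, 1)
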