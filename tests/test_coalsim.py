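import math

import numpy as np
import pytest
from scipy import stats as sps

from codiv.coalsim import (
    Genealogy,
    mutate_sequences,
    simulate_dataset,
    simulate_genealogy,
    transition_matrix,
)
from codiv.config_io import PriorSpec, uniform_config
from codiv.hyperprior import LocusParams, TaxonParams, draw_hyper

JC = LocusParams(rate_scalar=1.0, subst_model="JC")


def panmictic_params(theta):
    """tau = 0 with ancestral size theta: a single constant-size population
    of relative size 1 under the unit convention."""
    return TaxonParams(
        theta_a=theta, theta_a1=theta / 2, theta_a2=theta / 2,
        theta_b1=theta / 2, theta_b2=theta / 2,
        tau=0.0, tau_b1=0.0, tau_b2=0.0,
    )


def two_tip_tree(path_length):
    """Fixed two-leaf genealogy with total tip-to-tip path `path_length`."""
    t = path_length / 2
    return Genealogy(parent=np.array([2, 2, -1]),
                     time=np.array([0.0, 0.0, t]), n1=1, n2=1)


class TestGenealogy:
    def test_pairwise_tmrca_matches_constant_size_expectation(self, rng):
        # E[T2] = x/2 with x = 1: 0.5 units of 4N generations
        reps = 4000
        times = [
            simulate_genealogy(panmictic_params(0.004), 1, 1, rng).tmrca
            for _ in range(reps)
        ]
        se = 0.5 / math.sqrt(reps)  # exponential: SD = mean
        assert abs(np.mean(times) - 0.5) < 3 * se

    def test_no_cross_population_coalescence_before_tau_without_migration(self, rng):
        tp = TaxonParams(theta_a=0.005, theta_a1=0.002, theta_a2=0.002,
                         theta_b1=0.004, theta_b2=0.003, tau=1.5,
                         tau_b1=0.7, tau_b2=0.2, nm=0.0)
        for _ in range(2000):
            g = simulate_genealogy(tp, 2, 2, rng)
            assert g.first_cross_population_coalescence() >= tp.tau

    def test_trees_are_ultrametric_with_nonnegative_branches(self, rng):
        tp = TaxonParams(theta_a=0.005, theta_a1=0.002, theta_a2=0.002,
                         theta_b1=0.004, theta_b2=0.003, tau=1.0,
                         tau_b1=0.5, tau_b2=0.2, nm=2.0)
        for _ in range(200):
            g = simulate_genealogy(tp, 3, 3, rng)
            for node in range(len(g.time)):
                if g.parent[node] >= 0:
                    assert g.time[g.parent[node]] >= g.time[node]
            assert np.all(g.time[: g.n_tips] == 0.0)

    def test_strong_migration_approaches_panmixia(self, rng):
        # with coalescence rate 2/x_d and migration rate 4 Nm / x_d, the
        # strong-migration limit of the two-deme system is a single
        # population of relative size x_1 + x_2 = 1, for any size split
        theta = 0.004
        tp = TaxonParams(theta_a=theta, theta_a1=0.6 * theta,
                         theta_a2=0.4 * theta, theta_b1=0.6 * theta,
                         theta_b2=0.4 * theta, tau=50.0, tau_b1=0.0,
                         tau_b2=0.0, nm=100.0)
        reps = 1500
        structured = [simulate_genealogy(tp, 1, 1, rng).tmrca
                      for _ in range(reps)]
        panmictic = [simulate_genealogy(panmictic_params(theta), 1, 1, rng).tmrca
                     for _ in range(reps)]
        assert sps.ks_2samp(structured, panmictic).pvalue > 0.001

    def test_matches_independent_coalescent_implementation(self, rng):
        # constant-size sample of 6: compare the TMRCA distribution with
        # msprime under an equivalent parameterization (haploid samples,
        # population size chosen so E[T2] = 0.5)
        msprime = pytest.importorskip("msprime")
        reps = 1200
        mine = [simulate_genealogy(panmictic_params(0.004), 3, 3, rng).tmrca
                for _ in range(reps)]
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=6, ploidy=1, population_size=0.5,
                num_replicates=reps, random_seed=1234,
            )
        ]
        assert sps.ks_2samp(mine, theirs).pvalue > 0.001

    def test_all_zero_sizes_rejected(self, rng):
        tp = TaxonParams(theta_a=0.01, theta_a1=0.001, theta_a2=0.001,
                         theta_b1=0.0, theta_b2=0.0, tau=1.0,
                         tau_b1=0.0, tau_b2=0.0)
        with pytest.raises(ValueError, match="zero"):
            simulate_genealogy(tp, 2, 2, rng)


class TestMutation:
    def test_zero_theta_gives_identical_sequences(self, rng):
        g = simulate_genealogy(panmictic_params(0.004), 2, 2, rng)
        aln = mutate_sequences(g, 100, 0.0, JC, rng)
        assert (aln.matrix == aln.matrix[0]).all()

    def test_jukes_cantor_divergence_matches_closed_form(self, rng):
        # expected proportion of differing sites after d expected
        # substitutions of separation: (3/4)(1 - exp(-4d/3))
        rate, b, L = 0.01, 8.0, 200_000
        g = two_tip_tree(b)
        aln = mutate_sequences(g, L, rate, JC, rng)
        observed = (aln.matrix[0] != aln.matrix[1]).mean()
        expected = 0.75 * (1 - math.exp(-4.0 * rate * b / 3.0))
        se = math.sqrt(expected * (1 - expected) / L)
        assert abs(observed - expected) < 3 * se

    def test_inheritance_scalar_scales_divergence(self, rng):
        rate, b, L = 0.005, 4.0, 400_000
        g = two_tip_tree(b)
        full = mutate_sequences(g, L, rate, JC, rng)
        quarter = mutate_sequences(
            g, L, rate,
            LocusParams(rate_scalar=1.0, inheritance_scalar=0.25,
                        subst_model="JC"),
            rng,
        )
        p_full = (full.matrix[0] != full.matrix[1]).mean()
        p_quarter = (quarter.matrix[0] != quarter.matrix[1]).mean()
        # in the low-divergence regime expected differences scale ~linearly
        ratio = p_quarter / p_full
        assert 0.2 < ratio < 0.3

    @pytest.mark.parametrize("model,freqs,kappa", [
        ("JC", (0.25, 0.25, 0.25, 0.25), 1.0),
        ("F81", (0.4, 0.3, 0.2, 0.1), 1.0),
        ("HKY", (0.3, 0.2, 0.3, 0.2), 4.0),
    ])
    def test_transition_matrices_are_stochastic_and_stationary(self, model,
                                                               freqs, kappa):
        pi = np.array(freqs)
        for d in (0.01, 0.5, 3.0):
            P = transition_matrix(model, d, pi, kappa)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all()
            np.testing.assert_allclose(pi @ P, pi, atol=1e-12)

    def test_uniformization_agrees_with_transition_matrix(self, rng):
        # the event-based simulator must reproduce exp(Qd): check the
        # distribution of child states given parent state A on one branch
        pi = (0.3, 0.2, 0.3, 0.2)
        lp = LocusParams(rate_scalar=1.0, subst_model="HKY", kappa=4.0,
                         base_freqs=pi)
        d = 0.4
        g = two_tip_tree(2 * d)  # each branch has length d
        L = 100_000
        P = transition_matrix("HKY", d, pi, 4.0)
        aln = mutate_sequences(g, L, 1.0, lp, rng)
        # the two tips are conditionally independent given the root, so the
        # joint tip-state distribution is Pᵀ diag(pi) P
        joint = np.zeros((4, 4))
        for a, b in zip(aln.matrix[0], aln.matrix[1]):
            joint[a, b] += 1
        expected = P.T @ np.diag(pi) @ P * L
        chi = ((joint - expected) ** 2 / expected).sum()
        # 15 dof chi-square, generous threshold
        assert chi < sps.chi2.ppf(0.999, 15)

    def test_hky_kappa_enriches_transitions(self, rng):
        pi = (0.25, 0.25, 0.25, 0.25)
        d = 0.3
        P_high = transition_matrix("HKY", d, pi, 10.0)
        P_low = transition_matrix("HKY", d, pi, 1.0)
        # A->G is a transition; fraction of changes that are transitions
        # must grow with kappa
        frac_high = P_high[0, 2] / (1 - P_high[0, 0])
        frac_low = P_low[0, 2] / (1 - P_low[0, 0])
        assert frac_high > frac_low


class TestDataset:
    def test_minimal_dataset_shape(self, rng):
        config = uniform_config(1, 1, 1, 1, 50)
        h = draw_hyper(config, PriorSpec(), rng)
        ds = simulate_dataset(h, config, rng)
        assert ds.n_pairs == 1
        assert ds.alignments[0][0].matrix.shape == (2, 50)

    def test_simultaneous_divergence_shares_tau(self, rng):
        config = uniform_config(4, 1, 2, 2, 50)
        h = draw_hyper(config, PriorSpec(psi_fixed=1), rng)
        ds = simulate_dataset(h, config, rng)
        taus = {t.tau for t in ds.hyper.taxa}
        assert len(taus) == 1

    def test_full_config_shapes_match(self, rng):
        config = uniform_config(5, 3, 4, 3, 120)
        h = draw_hyper(config, PriorSpec(), rng)
        ds = simulate_dataset(h, config, rng)
        alns = [a for pair in ds.alignments for a in pair]
        assert len(alns) == 15
        for a in alns:
            assert a.matrix.shape == (7, 120)
            assert (a.n1, a.n2) == (4, 3)

    def test_mean_cross_divergence_increases_with_tau(self, rng):
        means = []
        for tau in (0.25, 1.5, 4.0):
            tp = TaxonParams(theta_a=0.004, theta_a1=0.002, theta_a2=0.002,
                             theta_b1=0.002, theta_b2=0.002, tau=tau,
                             tau_b1=0.0, tau_b2=0.0)
            tot = 0.0
            for _ in range(800):
                g = simulate_genealogy(tp, 1, 1, rng)
                aln = mutate_sequences(g, 300, 0.004, JC, rng)
                tot += (aln.matrix[0] != aln.matrix[1]).sum()
            means.append(tot / 800)
        assert means[0] < means[1] < means[2]
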