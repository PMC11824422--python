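"""Synthetic-data generators and their independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainsfs import engine
from strainsfs.demography import DemographicModel
from strainsfs.dfe import DFEModel
from strainsfs.synthetic import (OracleSFS, coalescent_sfs, forward_wf_sfs,
                                 prf_quadrature_sfs, random_coalescent_tree,
                                 simulate_bm_traits, simulate_host_pileup,
                                 simulate_sfs_counts, substream)


class TestSimulateSFSCounts:
    def test_poisson_mean_identity_for_singletons(self, scenario_factory):
        neutral = engine.expected_folded_sfs([1.0], [], 0.0, 14)
        theta = 100.0 / neutral[0]      # expected singletons = 100
        totals = []
        for seed in range(200):
            sc = scenario_factory(theta_s=theta, seed=seed)
            totals.append(simulate_sfs_counts(sc, "synonymous").counts[0])
        mean = np.mean(totals)
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(mean - 100.0) < 3 * se + 1e-9

    def test_determinism(self, scenario_factory):
        sc = scenario_factory(seed=33)
        a = simulate_sfs_counts(sc, "synonymous")
        b = simulate_sfs_counts(sc, "synonymous")
        assert np.array_equal(a.counts, b.counts)
        assert a.L == b.L and a.n == b.n

    def test_total_sites_match_prf_quadrature_expectation(
            self, scenario_factory):
        # Total segregating sites over many replicates: mean must agree
        # with the summed expectation from the independent stationary
        # quadrature oracle (GOF via Poisson z at alpha = 0.01).
        oracle = prf_quadrature_sfs(0.0, 14)
        theta = 30.0
        mu_total = theta * oracle.expectation.sum()
        totals = []
        for seed in range(500):
            sc = scenario_factory(theta_s=theta, seed=seed)
            totals.append(simulate_sfs_counts(sc, "synonymous").counts.sum())
        grand = np.sum(totals)
        z = (grand - 500 * mu_total) / np.sqrt(500 * mu_total)
        assert abs(z) < stats.norm.isf(0.005)

    def test_nonsyn_requires_dfe(self, scenario_factory):
        sc = scenario_factory(dfe=None)
        with pytest.raises(ValueError, match="DFE"):
            simulate_sfs_counts(sc, "nonsynonymous")

    def test_neutral_limit_agreement_between_generators(
            self, scenario_factory, eq_cache_n14):
        # A DFE that is a pure neutral point mass must reproduce the
        # synonymous generator's expectation bin by bin (chi-square GOF
        # over 500 replicates, alpha = 0.01).
        dfe = DFEModel("neu_gamma", shape=1.0, scale=1e-3, p_neu=1.0,
                       n_anc_ref=1e4)
        theta = 40.0
        acc = np.zeros(7)
        n_rep = 500
        for seed in range(n_rep):
            sc = scenario_factory(theta_s=theta, dfe=dfe, seed=seed)
            acc += simulate_sfs_counts(sc, "nonsynonymous").counts
        expected_bin = sc.theta_ns * engine.expected_folded_sfs(
            [1.0], [], 0.0, 14)
        chi2_stat = np.sum((acc - n_rep * expected_bin) ** 2
                           / (n_rep * expected_bin))
        assert chi2_stat < stats.chi2.isf(0.01, df=7)


class TestSimulateHostPileup:
    def test_no_mixture_full_recovery(self, scenario_factory):
        from strainsfs.phasing import call_quasi_phased
        sc = scenario_factory(strain_major_fraction=1.0, depth_mean=100.0,
                              genome_length=1500, theta_s=30.0, seed=9)
        calls, truth = simulate_host_pileup(sc)
        dominant = truth["dominant"]
        for host, grp in calls.groupby("host"):
            h = call_quasi_phased(grp)
            called = {p: a for (_, p), a in h.calls.items() if a is not None}
            assert len(called) == len(h.calls)   # nothing missing
            for p, a in called.items():
                assert a == dominant.loc[host, p]

    def test_missing_band_matches_binomial_tail(self, scenario_factory):
        # strain mixture 0.9/0.1, fixed depth 50: among sites where the
        # two within-host strains disagree, the fraction falling in the
        # missing band [0.5, 0.8) is the exact binomial tail.
        sc = scenario_factory(n_hosts=30, strain_major_fraction=0.9,
                              depth_mean=50.0, depth_sd=0.0,
                              genome_length=4000, theta_s=150.0, seed=21)
        calls, truth = simulate_host_pileup(sc)
        freq = calls.pivot_table(index="host", columns="pos0",
                                 values="major_freq").loc[
            truth["hosts"]].to_numpy()
        # exact oracle: reads ~ Binomial(50, 0.9) at discordant sites;
        # major_freq in [0.5, 0.8) iff reads strictly between 0.2n, 0.8n
        n = 50
        k = np.arange(0, n + 1)
        pmf = stats.binom.pmf(k, n, 0.9)
        p_missing = pmf[(k > 0.2 * n) & (k < 0.8 * n)].sum()
        disc = _discordant_mask(sc, truth)
        band = (freq >= 0.5) & (freq < 0.8)
        frac = band[disc].mean()
        se = np.sqrt(p_missing * (1 - p_missing) / disc.sum())
        assert abs(frac - p_missing) < 4 * se

    def test_majority_missing_at_06(self, scenario_factory):
        sc = scenario_factory(n_hosts=30, strain_major_fraction=0.6,
                              depth_mean=50.0, depth_sd=0.0,
                              genome_length=4000, theta_s=150.0, seed=22)
        calls, truth = simulate_host_pileup(sc)
        freq = calls.pivot_table(index="host", columns="pos0",
                                 values="major_freq").loc[
            truth["hosts"]].to_numpy()
        disc = _discordant_mask(sc, truth)
        assert disc.sum() > 50
        missing = freq[disc] < 0.8
        assert missing.mean() > 0.5

    def test_determinism(self, scenario_factory):
        sc = scenario_factory(seed=77, genome_length=800)
        a, _ = simulate_host_pileup(sc)
        b, _ = simulate_host_pileup(sc)
        pd.testing.assert_frame_equal(a, b)

    def test_depth_below_one_rejected(self, scenario_factory):
        sc = scenario_factory(depth_mean=0.5)
        with pytest.raises(ValueError):
            simulate_host_pileup(sc)


def _discordant_mask(sc, truth):
    """Host x site mask of sites where the host's two strains disagree."""
    dom = truth["dominant"].to_numpy()
    # partner assignment is reproducible through the named substream
    part_rng = substream(sc.seed, "pileup:mixture")
    partner = part_rng.integers(0, sc.n_hosts, size=sc.n_hosts)
    same = partner == np.arange(sc.n_hosts)
    partner[same] = (partner[same] + 1) % sc.n_hosts
    sec = dom[partner]
    return dom != sec


class TestForwardWF:
    def test_neutral_matches_closed_form(self):
        oracle = forward_wf_sfs(N=600, gamma=0.0, n=14, reps=15000, seed=4)
        i = np.arange(1, 8)
        exact = 1.0 / i + 1.0 / (14 - i)
        exact[-1] = 1.0 / 7
        z = (oracle.expectation - exact) / oracle.mc_stderr
        assert np.all(np.abs(z) < 3.0), z

    def test_purifying_selection_depletes_every_bin(self):
        neutral = forward_wf_sfs(N=600, gamma=0.0, n=14, reps=15000, seed=4)
        sel = forward_wf_sfs(N=600, gamma=-10.0, n=14, reps=15000, seed=5)
        # allow 3 joint MC standard errors of slack per bin
        slack = 3 * np.hypot(neutral.mc_stderr, sel.mc_stderr)
        assert np.all(sel.expectation <= neutral.expectation + slack)
        # proportional deficit grows with frequency
        ratio = sel.expectation / neutral.expectation
        assert ratio[-1] < ratio[0]

    def test_equilibrium_matches_quadrature(self):
        oracle = forward_wf_sfs(N=600, gamma=-5.0, n=14, reps=15000, seed=6)
        quad = prf_quadrature_sfs(-5.0, 14)
        z = (oracle.expectation - quad.expectation) / oracle.mc_stderr
        assert np.all(np.abs(z) < 3.0), z

    def test_desk_scale_precondition(self):
        with pytest.raises(ValueError):
            forward_wf_sfs(N=5000, gamma=0.0, n=14)


class TestOracleSFS:
    def test_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            OracleSFS(np.array([-1.0]), np.array([0.0]), "prf_quadrature")

    def test_quadrature_neutral_equals_closed_form(self):
        q = prf_quadrature_sfs(0.0, 14)
        i = np.arange(1, 8)
        exact = 1.0 / i + 1.0 / (14 - i)
        exact[-1] = 1.0 / 7
        assert np.allclose(q.expectation, exact, rtol=1e-8)
        assert np.all(q.mc_stderr == 0.0)


class TestSimulateBMTraits:
    def test_lambda_zero_gives_diagonal_covariance(self):
        tree = random_coalescent_tree(8, seed=1)
        draws = np.array([
            simulate_bm_traits(tree, 0.0, 1.0, seed=s).to_numpy()
            for s in range(400)
        ])
        cov = np.cov(draws.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 0.3 * np.max(np.diag(cov))

    def test_determinism(self, tree30):
        a = simulate_bm_traits(tree30, 0.7, 2.0, seed=11)
        b = simulate_bm_traits(tree30, 0.7, 2.0, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_star_tree_rejected(self):
        star = "(" + ",".join(f"t{i}:1.0" for i in range(6)) + ");"
        with pytest.raises(ValueError, match="star"):
            simulate_bm_traits(star, 0.5, 1.0, seed=0)

    def test_lambda_one_recovery(self, tree30):
        # Parameter recovery: median ML lambda over replicates near 1.
        from strainsfs.phylo import pagels_lambda
        est = []
        for s in range(60):
            traits = simulate_bm_traits(tree30, 1.0, 1.0, seed=s)
            est.append(pagels_lambda(tree30, traits).lambda_hat)
        assert 0.85 <= np.median(est)


class TestSubstreams:
    def test_named_substreams_are_independent(self):
        a = substream(1, "x").standard_normal(5)
        b = substream(1, "y").standard_normal(5)
        a2 = substream(1, "x").standard_normal(5)
        assert np.array_equal(a, a2)
        assert not np.array_equal(a, b)
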