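"""Multisite beta-diversity partition, resampling and comparisons."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mossgrad as mg
from mossgrad.beta import BetaSampleDistribution
from mossgrad.errors import UndefinedStatisticError

from conftest import random_species_grid


def incidence(rows):
    """Sites from species-name sets, e.g. [{'a','b'}, {'b'}]."""
    species = sorted(set().union(*rows))
    M = np.zeros((len(rows), len(species)), dtype=bool)
    for i, r in enumerate(rows):
        for s in r:
            M[i, species.index(s)] = True
    return M


def brute_force_partition(occ):
    """Independent oracle: explicit set arithmetic over all site pairs."""
    sites = [set(np.flatnonzero(row)) for row in occ]
    n = len(sites)
    smin = smax = 0
    for i in range(n):
        for j in range(i + 1, n):
            b_ij = len(sites[i] - sites[j])
            b_ji = len(sites[j] - sites[i])
            smin += min(b_ij, b_ji)
            smax += max(b_ij, b_ji)
    pooled = len(set().union(*sites))
    D = sum(len(s) for s in sites) - pooled
    sim = smin / (D + smin) if D + smin else 0.0
    sor = ((smin + smax) / (2 * D + smin + smax)
           if 2 * D + smin + smax else 0.0)
    return sor, sim, sor - sim


class TestPairwiseComponents:
    def test_worked_example(self):
        M = incidence([{"s1", "s2", "s3"}, {"s2", "s3", "s4"}])
        assert mg.pairwise_components(M, 0, 1) == (2, 1, 1)

    def test_identical_sites(self):
        M = incidence([{"a", "b", "c"}, {"a", "b", "c"}])
        assert mg.pairwise_components(M, 0, 1) == (3, 0, 0)

    def test_matches_set_operation_oracle(self, rng):
        M = rng.random((2, 30)) < 0.5
        a, bij, bji = mg.pairwise_components(M, 0, 1)
        s0, s1 = set(np.flatnonzero(M[0])), set(np.flatnonzero(M[1]))
        assert (a, bij, bji) == (len(s0 & s1), len(s0 - s1), len(s1 - s0))
        assert a + bij == M[0].sum()


class TestMultisitePartition:
    def test_perfectly_nested_three_sites(self):
        M = incidence([{"s1", "s2", "s3", "s4"}, {"s1", "s2"},
                       {"s1", "s2", "s3"}])
        p = mg.multisite_partition(M)
        assert p.beta_sim == 0.0
        assert p.beta_sor == pytest.approx(4 / 14)
        assert p.beta_sne == pytest.approx(4 / 14)

    def test_two_disjoint_sites_are_pure_turnover(self):
        M = incidence([{"s1", "s2"}, {"s3", "s4"}])
        p = mg.multisite_partition(M)
        assert (p.beta_sim, p.beta_sor, p.beta_sne) == (1.0, 1.0, 0.0)

    def test_two_sites_reduce_to_pairwise_sorensen_and_simpson(self):
        M = incidence([{"s1", "s2", "s3"}, {"s2", "s3", "s4"}])
        p = mg.multisite_partition(M)
        assert p.beta_sor == pytest.approx(1 / 3)
        assert p.beta_sim == pytest.approx(1 / 3)
        assert p.beta_sne == pytest.approx(0.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(UndefinedStatisticError):
            mg.multisite_partition(np.zeros((3, 4), dtype=bool))
        with pytest.raises(UndefinedStatisticError):
            mg.multisite_partition(np.ones((1, 4), dtype=bool))

    @given(arrays(bool, (6, 12)))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_additivity_bounds_and_oracle(self, M):
        if not M.any():
            return
        p = mg.multisite_partition(M)
        assert p.beta_sor == pytest.approx(p.beta_sim + p.beta_sne,
                                           abs=1e-12)
        assert 0.0 <= p.beta_sim <= p.beta_sor <= 1.0
        sor, sim, sne = brute_force_partition(M)
        assert p.beta_sor == pytest.approx(sor, abs=1e-12)
        assert p.beta_sim == pytest.approx(sim, abs=1e-12)

    @given(arrays(bool, (5, 10)), st.permutations(range(5)),
           st.permutations(range(10)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_to_site_and_species_order(self, M, site_perm,
                                                 sp_perm):
        if not M.any():
            return
        p = mg.multisite_partition(M)
        q = mg.multisite_partition(M[np.array(site_perm)][:, np.array(sp_perm)])
        assert p.beta_sor == pytest.approx(q.beta_sor, abs=1e-12)
        assert p.beta_sim == pytest.approx(q.beta_sim, abs=1e-12)

    def test_agrees_with_vegan_reference(self, rng, tmp_path):
        """Independent R implementation (vegan::nestedbetasor) on a random
        incidence matrix."""
        M = rng.random((8, 20)) < 0.4
        M[0, 0] = True  # guarantee non-empty
        path = tmp_path / "mat.csv"
        np.savetxt(path, M.astype(int), fmt="%d", delimiter=",")
        out = subprocess.run(
            ["Rscript", "-e",
             f'a <- as.matrix(read.csv("{path}", header=FALSE));'
             'cat(sprintf("%.15g", vegan::nestedbetasor(a)), sep="\\n")'],
            capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        r_sim, r_sne, r_sor = map(float, out.stdout.split())
        p = mg.multisite_partition(M)
        assert p.beta_sim == pytest.approx(r_sim, abs=1e-10)
        assert p.beta_sne == pytest.approx(r_sne, abs=1e-10)
        assert p.beta_sor == pytest.approx(r_sor, abs=1e-10)


class TestBetaSample:
    def test_region_of_exactly_subset_size_has_zero_variance(self, rng):
        grid = mg.LatticeGrid.regular(5, 4, lat_range=(47.0, 52.0))
        sg = random_species_grid(grid, 10, rng)
        mask = mg.split_regions(grid, 46.0)  # everything north
        d = mg.beta_sample(sg, mask, "north", sites_per_sample=20,
                           n_samples=50, seed=1)
        assert np.ptp(d.beta_sim) == 0.0
        assert np.ptp(d.beta_sne) == 0.0

    def test_nested_generator_yields_zero_turnover_in_every_sample(self):
        env = mg.make_landscape(10, 10, seed=4)
        cfg = mg.SimulationConfig(n_species=15, theta=1.0, noise=0.0, seed=4)
        truth = mg.simulate_truth(mg.simulate_pool(cfg, env), env, seed=5)
        d = mg.beta_sample(truth, None, "all", sites_per_sample=30,
                           n_samples=100, seed=2)
        assert np.all(d.beta_sim == 0.0)

    def test_mean_is_stable_across_seeds(self, rng):
        grid = mg.LatticeGrid.regular(10, 10)
        sg = random_species_grid(grid, 20, rng)
        a = mg.beta_sample(sg, None, "all", 30, 400, seed=1)
        b = mg.beta_sample(sg, None, "all", 30, 400, seed=2)
        se = a.beta_sim.std() / np.sqrt(400)
        assert abs(a.beta_sim.mean() - b.beta_sim.mean()) < 6 * se

    def test_region_smaller_than_subset_raises(self, rng):
        grid = mg.LatticeGrid.regular(4, 4)
        sg = random_species_grid(grid, 5, rng)
        mask = mg.split_regions(grid, 46.0)
        with pytest.raises(ValueError, match="smaller subset"):
            mg.beta_sample(sg, mask, "north", sites_per_sample=100)

    def test_deterministic_given_seed(self, rng):
        grid = mg.LatticeGrid.regular(8, 8)
        sg = random_species_grid(grid, 12, rng)
        a = mg.beta_sample(sg, None, "all", 20, 50, seed=9)
        b = mg.beta_sample(sg, None, "all", 20, 50, seed=9)
        assert np.array_equal(a.beta_sim, b.beta_sim)


def dist(values, region="all", group=""):
    values = np.asarray(values, dtype=float)
    return BetaSampleDistribution(group, region, 50, len(values), values,
                                  values.copy(), values.copy(), 0)


class TestCompareDistributions:
    def test_identical_distributions(self):
        a = dist([0.1, 0.2, 0.3])
        r = mg.compare_distributions(a, dist([0.1, 0.2, 0.3]), "beta_sim")
        assert (r.direction, r.p) == ("=", 1.0)

    def test_complete_separation_hits_the_floor(self, rng):
        a = dist(rng.random(1000) + 2.0)
        b = dist(rng.random(1000))
        r = mg.compare_distributions(a, b, "beta_sim")
        assert r.direction == ">"
        assert r.p == pytest.approx(1 / 1000)

    def test_p_matches_brute_force_pair_count(self, rng):
        va = rng.normal(0.3, 1.0, size=500)
        vb = rng.normal(0.0, 1.0, size=500)
        r = mg.compare_distributions(dist(va), dist(vb), "beta_sim")
        m = int(np.sum(va > vb))
        expected = max(min(2 * min(m / 500, 1 - m / 500), 1.0), 1 / 500)
        assert r.p == pytest.approx(expected)

    def test_direction_follows_median_difference(self, rng):
        va = rng.random(200)
        r = mg.compare_distributions(dist(va + 0.2), dist(va), "beta_sne")
        assert r.direction == ">"
        r2 = mg.compare_distributions(dist(va), dist(va + 0.2), "beta_sne")
        assert r2.direction == "<"
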