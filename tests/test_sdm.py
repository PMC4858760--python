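"""Predictor screening, evaluation metrics, binarization, consensus,
stacking and per-species ensemble fits."""

import numpy as np
import pytest

import mossgrad as mg
from mossgrad.errors import UndefinedStatisticError
from mossgrad.synthetic import EnvStack


def env_from(grid, **layers):
    return EnvStack(grid, {k: np.asarray(v, float) for k, v in layers.items()})


def corr_noise(rng, base, rho):
    """A vector correlated with ``base`` at approximately ``rho``."""
    noise = rng.normal(size=base.size)
    noise -= noise.mean()
    b = (base - base.mean()) / base.std()
    v = rho * b + np.sqrt(1 - rho**2) * noise / noise.std()
    return v


class TestScreenPredictors:
    def test_pair_above_threshold_keeps_exactly_one(self, grid10, rng):
        a = rng.normal(size=grid10.n_land)
        b = corr_noise(rng, a, 0.85)
        env = env_from(grid10, a=a, b=b)
        out = mg.screen_predictors(env, r_max=0.8)
        assert len(out.retained) == 1

    def test_orthogonal_layers_are_all_retained(self, grid10, rng):
        env = env_from(grid10, **{f"l{k}": rng.normal(size=grid10.n_land)
                                  for k in range(4)})
        out = mg.screen_predictors(env, r_max=0.8)
        assert set(out.retained) == set(env.names)

    def test_chain_leaves_no_retained_pair_above_threshold(self, grid10,
                                                           rng):
        a = rng.normal(size=grid10.n_land)
        b = corr_noise(rng, a, 0.9)
        c = corr_noise(rng, b, 0.9)
        env = env_from(grid10, a=a, b=b, c=c)
        out = mg.screen_predictors(env, r_max=0.8)
        # exhaustive recheck of every retained pair
        X = env.matrix(out.retained)
        R = np.corrcoef(X, rowvar=False)
        if R.ndim == 2:
            off = np.abs(R - np.eye(len(out.retained)))
            assert off.max() <= 0.8

    def test_constant_layer_is_excluded_with_log_entry(self, grid10, rng):
        env = env_from(grid10, flat=np.ones(grid10.n_land),
                       a=rng.normal(size=grid10.n_land),
                       b=rng.normal(size=grid10.n_land))
        out = mg.screen_predictors(env)
        assert "flat" not in out.retained
        assert any("flat" in entry for entry in out.log)


class TestEvaluate:
    def test_perfect_prediction_scores_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = mg.evaluate(y.astype(float), y)
        assert s.auc == 1.0
        assert s.tss == 1.0

    def test_constant_prediction_is_uninformative(self):
        y = np.array([0, 1, 0, 1])
        s = mg.evaluate(np.full(4, 0.7), y)
        assert s.auc == 0.5
        assert s.tss == 0.0

    def test_auc_equals_mann_whitney_pair_counting(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        pred = rng.random(40)
        s = mg.evaluate(pred, y)
        pos = pred[y == 1]
        neg = pred[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert s.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_max_tss_threshold_matches_exhaustive_scan(self, rng):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 0, 1])
        pred = rng.random(10)
        s = mg.evaluate(pred, y)
        best = -np.inf
        for thr in np.unique(pred):
            b = pred >= thr
            sens = (b & (y == 1)).sum() / (y == 1).sum()
            spec = (~b & (y == 0)).sum() / (y == 0).sum()
            best = max(best, sens + spec - 1)
        assert s.tss == pytest.approx(best)
        b = pred >= s.thr_max_tss
        sens = (b & (y == 1)).sum() / (y == 1).sum()
        spec = (~b & (y == 0)).sum() / (y == 0).sum()
        assert sens + spec - 1 == pytest.approx(best)

    def test_single_class_labels_raise(self):
        with pytest.raises(UndefinedStatisticError):
            mg.evaluate(np.array([0.2, 0.4]), np.array([1, 1]))


class TestBinarizeConsensusStack:
    def test_binarize_is_a_half_open_threshold(self):
        assert np.array_equal(mg.binarize(np.array([0.4, 0.5, 0.6]), 0.5),
                              [False, True, True])

    def test_unanimous_members_equal_any_member(self, rng):
        m = rng.random(20) < 0.5
        assert np.array_equal(mg.consensus([m, m, m]), m)

    def test_seven_of_twelve_votes_is_present(self):
        members = [np.array([True])] * 7 + [np.array([False])] * 5
        assert mg.consensus(members)[0]

    def test_exact_tie_resolves_to_absence(self):
        members = [np.array([True])] * 6 + [np.array([False])] * 6
        assert not mg.consensus(members)[0]

    def test_weighted_vote_uses_weights(self):
        members = [np.array([True]), np.array([False])]
        assert mg.consensus(members, weights=[3.0, 1.0])[0]
        assert not mg.consensus(members, weights=[1.0, 3.0])[0]

    def test_stack_matches_elementwise_sum(self, grid4, rng):
        maps = [rng.random(grid4.n_land) < 0.5 for _ in range(3)]
        ens = [mg.EnsembleResult(f"s{k}", {}, {}, m, {})
               for k, m in enumerate(maps)]
        stacked = mg.stack(ens, grid4)
        assert np.array_equal(stacked.richness,
                              np.sum(maps, axis=0).astype(float))

    def test_stack_monotone_in_species(self, grid4, rng):
        maps = [rng.random(grid4.n_land) < 0.5 for _ in range(4)]
        ens = [mg.EnsembleResult(f"s{k}", {}, {}, m, {})
               for k, m in enumerate(maps)]
        r3 = mg.stack(ens[:3], grid4).richness
        r4 = mg.stack(ens, grid4).richness
        assert np.all(r4 >= r3)

    def test_empty_stack_is_all_zero(self, grid4):
        assert mg.stack([], grid4).richness.sum() == 0.0


@pytest.fixture
def separable_setup(rng):
    """A species present exactly where temperature exceeds its median,
    with temperature as the sole predictor."""
    grid = mg.LatticeGrid.regular(12, 12)
    temp = np.linspace(0, 10, grid.n_land) + rng.normal(0, 0.01,
                                                        grid.n_land)
    env = env_from(grid, temperature=temp)
    occ = (temp > np.median(temp))[:, None]
    sg = mg.SpeciesGrid(grid, ["warm"], occ)
    return sg, env


class TestFitSpecies:
    def test_separable_species_scores_perfectly(self, separable_setup):
        sg, env = separable_setup
        cfg = mg.SDMConfig(n_replicates=4, n_trees=50, seed=1)
        for tech in ("glm", "rf", "maxent"):
            fit = mg.fit_species(sg, "warm", env, tech, cfg)
            assert len(fit.replicates) == 4
            for rf in fit.replicates:
                assert rf.scores.auc == 1.0
                assert rf.scores.tss == 1.0

    def test_random_labels_give_chance_level_auc(self, rng):
        grid = mg.LatticeGrid.regular(15, 15)
        env = env_from(grid, a=rng.normal(size=grid.n_land),
                       b=rng.normal(size=grid.n_land))
        occ = (rng.random(grid.n_land) < 0.5)[:, None]
        sg = mg.SpeciesGrid(grid, ["coin"], occ)
        cfg = mg.SDMConfig(n_replicates=10, seed=2)
        fit = mg.fit_species(sg, "coin", env, "glm", cfg)
        mean_auc = np.mean([r.scores.auc for r in fit.replicates])
        assert abs(mean_auc - 0.5) < 0.05

    def test_split_fractions_and_disjointness(self, separable_setup):
        sg, env = separable_setup
        cfg = mg.SDMConfig(n_replicates=3, seed=1)
        fit = mg.fit_species(sg, "warm", env, "glm", cfg)
        for rf in fit.replicates:
            assert len(set(rf.train_idx) & set(rf.test_idx)) == 0
            n = len(rf.train_idx) + len(rf.test_idx)
            assert len(rf.train_idx) / n == pytest.approx(0.7, abs=0.05)

    def test_deterministic_given_seed(self, separable_setup):
        sg, env = separable_setup
        cfg = mg.SDMConfig(n_replicates=2, seed=5)
        a = mg.fit_species(sg, "warm", env, "rf", cfg)
        b = mg.fit_species(sg, "warm", env, "rf", cfg)
        assert np.array_equal(a.replicates[0].prediction,
                              b.replicates[0].prediction)


class TestEnsembleSpecies:
    def test_member_count_and_consensus_binary(self, separable_setup):
        sg, env = separable_setup
        cfg = mg.SDMConfig(techniques=("glm", "maxent"), n_replicates=3,
                           seed=1)
        res = mg.ensemble_species(sg, "warm", env, cfg)
        assert len(res.members) == 2 * 3 * 2  # techniques x reps x rules
        assert res.consensus_map.dtype == bool
        # separable species: consensus reproduces the true range except,
        # at most, pixels sitting right on the decision boundary (where
        # the test-derived threshold is genuinely ambiguous)
        temp = env.layers["temperature"]
        mismatch = res.consensus_map != sg.occupancy[:, 0]
        assert mismatch.mean() <= 0.02
        assert np.all(np.abs(temp[mismatch] - np.median(temp)) < 0.2)

    def test_evaluation_table_is_tidy(self, separable_setup):
        sg, env = separable_setup
        cfg = mg.SDMConfig(techniques=("glm",), n_replicates=2, seed=1)
        tab = mg.ensemble_species(sg, "warm", env, cfg).evaluation_table()
        assert set(tab.columns) >= {"species", "technique", "replicate",
                                    "auc", "tss"}
        assert len(tab) == 2
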