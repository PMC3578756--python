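"""Simulator core: initialization, gamete formation, generation stepping,
determinism and neutral-theory calibration."""

import numpy as np
import pytest

from ralesim import SimParams, evolve, initialize_population, make_gamete, next_generation
from ralesim.popgen import diversity


def desk_params(**kw):
    base = dict(N=100, theta=20, theta_d=2, rho=20, lambda_effect=0.0,
                n_generations=0, seed=0)
    base.update(kw)
    return SimParams.from_scaled(**base)


class TestParams:
    def test_scaled_parameterization_preserves_theta_rho(self):
        p = SimParams.from_scaled(N=1000, theta=100, theta_d=10, rho=100,
                                  lambda_effect=0.1)
        assert p.mu_neutral == pytest.approx(100 / 4000)
        assert p.theta == pytest.approx(100)
        assert p.theta_d == pytest.approx(10)
        assert p.rho == pytest.approx(100)
        assert p.n_generations == 8000

    def test_full_scale_defaults(self):
        p = SimParams.full_scale(lambda_effect=0.075)
        assert (p.N, p.mu_neutral, p.mu_causative, p.r) == (20000, 0.00125, 0.000125, 0.00125)
        assert p.n_generations == 8 * 20000

    @pytest.mark.parametrize("bad", [dict(N=0), dict(mu_neutral=-1e-3),
                                     dict(sigma_s=0.0), dict(n_generations=-1)])
    def test_invalid_params_rejected(self, bad):
        kw = dict(N=10, mu_neutral=0.01, mu_causative=0.001, r=0.01,
                  lambda_effect=0.1, n_generations=10)
        kw.update(bad)
        with pytest.raises(ValueError):
            SimParams(**kw)


class TestInitialize:
    def test_mutation_free_start(self):
        pop = initialize_population(desk_params(N=5))
        assert pop.n_haplotypes == 10
        assert pop.n_mutations == 0
        assert pop.mutation_table().empty

    def test_population_size_matches(self):
        pop = initialize_population(desk_params(N=20000))
        assert pop.n_haplotypes == 40000


class TestMakeGamete:
    def test_no_event_limit_copies_one_parent(self):
        p = SimParams(N=10, mu_neutral=0, mu_causative=0, r=0,
                      lambda_effect=0, n_generations=0)
        rng = np.random.default_rng(0)
        a = np.array([1, 0, 1, 0], dtype=np.uint8)
        b = np.array([0, 1, 0, 1], dtype=np.uint8)
        pos = np.array([0.1, 0.3, 0.5, 0.7])
        for _ in range(20):
            g, new = make_gamete(a, b, pos, p, rng)
            assert not new
            assert (g == a).all() or (g == b).all()

    def test_single_breakpoint_splits_parents(self):
        # force exactly one crossover by a huge r then condition on n_x == 1
        p = SimParams(N=10, mu_neutral=0, mu_causative=0, r=1.0,
                      lambda_effect=0, n_generations=0)
        rng = np.random.default_rng(5)
        a = np.ones(6, dtype=np.uint8)
        b = np.zeros(6, dtype=np.uint8)
        pos = np.linspace(0.05, 0.95, 6)
        seen = 0
        while seen < 10:
            g, _ = make_gamete(a, b, pos, p, rng)
            u = np.flatnonzero(np.diff(g.astype(int)))
            if len(set(g.tolist())) == 2:
                seen += 1
                # one contiguous switch between all-A and all-B segments
                assert u.size >= 1

    def test_causative_effect_mean_matches_exponential(self):
        p = SimParams(N=10, mu_neutral=0, mu_causative=2.0, r=0,
                      lambda_effect=0.1, n_generations=0)
        rng = np.random.default_rng(7)
        effs = []
        for _ in range(3000):
            _, new = make_gamete(np.zeros(0, np.uint8), np.zeros(0, np.uint8),
                                 np.zeros(0), p, rng)
            effs += [e for _, e, c in new if c]
        effs = np.array(effs)
        assert effs.mean() == pytest.approx(0.1, rel=0.05)


class TestNextGeneration:
    def test_single_parent_clones_itself(self):
        p = SimParams(N=1, mu_neutral=0, mu_causative=0, r=0,
                      lambda_effect=0, n_generations=0, seed=3)
        pop = initialize_population(p)
        child = next_generation(pop, rng=np.random.default_rng(3))
        assert child.n_mutations == 0
        assert child.generation == 1

    def test_strong_selection_keeps_causative_rare(self):
        """Across paired replicates, strong selection (large effects) keeps
        causative mean frequency below the matched neutral (lambda=0) runs."""
        def mean_freq(lam, seed):
            p = SimParams.from_scaled(N=100, theta=0, theta_d=5, rho=5,
                                      lambda_effect=lam, no_neutral=True,
                                      n_generations=800, seed=seed)
            pop = evolve(p)
            if pop.n_mutations == 0:
                return np.nan
            return (pop.counts / pop.n_haplotypes).mean()

        sel = np.nanmean([mean_freq(2.0, 100 + i) for i in range(8)])
        neu = np.nanmean([mean_freq(0.0, 100 + i) for i in range(8)])
        assert sel < neu


def test_neutral_fixation_probability():
    """Fixation probability of a neutral allele ~ its frequency (WF oracle).

    The allele is flagged causative with effect 0 (phenotypically silent),
    so a fixation is recorded in the fixation log rather than silently
    dropped, cleanly separating fixation from loss.
    """
    N, k = 10, 5
    n_runs = 400
    rng = np.random.default_rng(17)
    p = SimParams(N=N, mu_neutral=0, mu_causative=0, r=0,
                  lambda_effect=0, n_generations=0, seed=0)
    fixed = 0
    for _ in range(n_runs):
        pop = initialize_population(p)
        H = np.zeros((2 * N, 1), dtype=np.uint8)
        H[rng.choice(2 * N, k, replace=False), 0] = 1
        pop.haplotypes = H
        pop.positions = np.array([0.5])
        pop.effects = np.array([0.0])
        pop.is_causative = np.array([True])
        pop.origins = np.array([0], dtype=np.int64)
        pop.counts = np.array([k], dtype=np.int64)
        while pop.n_mutations:
            pop = next_generation(pop, rng=rng)
        fixed += bool(pop.fixations)
    # expectation k/2N = 0.25; n=400 -> binomial SE ~ 0.022, allow 4 SE
    assert fixed / n_runs == pytest.approx(k / (2 * N), abs=0.09)


class TestEvolve:
    def test_zero_generations_returns_initial_state(self):
        pop = evolve(desk_params(N=10))
        assert pop.generation == 0
        assert pop.n_mutations == 0

    def test_determinism_identical_seeds(self):
        p = desk_params(N=50, lambda_effect=0.1, n_generations=150, seed=77)
        a = evolve(p)
        b = evolve(p)
        assert (a.haplotypes == b.haplotypes).all()
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.effects, b.effects)
        assert np.array_equal(a.counts, b.counts)

    def test_count_bookkeeping_and_infinite_sites(self, tiny_pop):
        assert (tiny_pop.recompute_counts() == tiny_pop.counts).all()
        assert np.unique(tiny_pop.positions).size == tiny_pop.n_mutations
        assert tiny_pop.counts.min() >= 1
        assert tiny_pop.counts.max() <= tiny_pop.n_haplotypes

    def test_columns_sorted_by_position(self, tiny_pop):
        assert (np.diff(tiny_pop.positions) > 0).all()

    def test_all_zero_fitness_guard(self):
        p = desk_params(N=5, n_generations=1)
        pop = initialize_population(p)
        pop.optimum = 1e6  # absurd optimum: fitness underflows to 0
        with pytest.raises(RuntimeError):
            next_generation(pop, rng=np.random.default_rng(0))


class TestNeutralCalibration:
    """Equilibrium diversity matches neutral coalescent expectations."""

    N = 100
    THETA = 5.0
    N_REPS = 50

    @pytest.fixture(scope="class")
    def replicate_stats(self):
        pis, Ss = [], []
        for rep in range(self.N_REPS):
            p = SimParams.from_scaled(N=self.N, theta=0.0, theta_d=self.THETA,
                                      rho=5.0, lambda_effect=0.0,
                                      no_neutral=True, seed=9000 + rep)
            pop = evolve(p)
            d = diversity(pop.haplotypes, pop.is_causative, "causative")
            pis.append(d["pi"])
            Ss.append(d["S"])
        return np.array(pis), np.array(Ss)

    def test_mean_pi_matches_theta(self, replicate_stats):
        pis, _ = replicate_stats
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - self.THETA) < 3 * se + 0.02 * self.THETA

    def test_mean_segregating_sites_matches_watterson(self, replicate_stats):
        _, Ss = replicate_stats
        n = 2 * self.N
        expected = self.THETA * np.sum(1.0 / np.arange(1, n))
        se = Ss.std(ddof=1) / np.sqrt(len(Ss))
        assert abs(Ss.mean() - expected) < 3 * se + 0.02 * expected

    def test_neutral_diversity_insensitive_to_selection(self, tiny_pop, null_pop):
        """Purifying selection on the causative class leaves neutral-class
        diversity statistically unchanged."""
        d1 = diversity(tiny_pop.haplotypes, tiny_pop.is_causative, "neutral")
        d0 = diversity(null_pop.haplotypes, null_pop.is_causative, "neutral")
        # both should be within a loose factor of theta=20; single
        # replicates have high variance, so only a sanity window
        for d in (d0, d1):
            assert 5 < d["pi"] < 60
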