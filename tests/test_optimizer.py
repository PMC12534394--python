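"""Immune-genetic optimizer: sorting oracles, operator statistics, recovery."""

import math

import numpy as np
import pytest

from neutrodent.optimizer import (
    GIOConfig,
    Individual,
    ParetoArchive,
    clonal_expand,
    crossover,
    crowding_distance,
    dominates,
    hypermutate,
    mutate,
    negative_selection,
    nondominated_sort,
    run_gio,
    tournament_select,
)
from neutrodent.membership import AgeGroup

BOUNDS = np.array([[0.0, 1.0], [0.0, 1.0]])


def ind(*objectives, genome=None):
    g = np.zeros(2) if genome is None else np.asarray(genome, dtype=float)
    return Individual(genome=g, objectives=np.array(objectives, dtype=float))


def brute_force_fronts(pop):
    """O(n^3) oracle: peel non-dominated sets repeatedly."""
    remaining = list(pop)
    fronts = []
    while remaining:
        front = [
            a for a in remaining
            if not any(dominates(b.objectives, a.objectives) for b in remaining)
        ]
        fronts.append({id(x) for x in front})
        remaining = [x for x in remaining if id(x) not in fronts[-1]]
    return fronts


class TestNondominatedSort:
    def test_single_individual(self):
        fronts = nondominated_sort([ind(1.0, 2.0)])
        assert len(fronts) == 1 and fronts[0][0].rank == 0

    def test_hand_worked_three_points(self):
        a, b, c = ind(1, 2), ind(2, 1), ind(3, 3)
        fronts = nondominated_sort([a, b, c])
        assert {id(x) for x in fronts[0]} == {id(a), id(b)}
        assert {id(x) for x in fronts[1]} == {id(c)}
        assert c.rank == 1

    @pytest.mark.parametrize("n_obj", [2, 3, 4])
    def test_agrees_with_brute_force_oracle(self, n_obj):
        rng = np.random.default_rng(n_obj)
        for _ in range(40):
            pop = [ind(*rng.uniform(0, 1, n_obj)) for _ in range(rng.integers(2, 31))]
            fast = nondominated_sort(pop)
            slow = brute_force_fronts(pop)
            assert len(fast) == len(slow)
            for ff, sf in zip(fast, slow):
                assert {id(x) for x in ff} == sf


class TestCrowdingDistance:
    def test_small_fronts_all_infinite(self):
        for front in ([ind(1, 1)], [ind(1, 2), ind(2, 1)]):
            assert np.all(np.isinf(crowding_distance(front)))

    def test_equally_spaced_collinear_hand_value(self):
        front = [ind(0.0, 1.0), ind(0.5, 0.5), ind(1.0, 0.0)]
        d = crowding_distance(front)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_permutation_invariance(self, rng):
        front = [ind(*rng.uniform(0, 1, 2)) for _ in range(8)]
        d = crowding_distance(front)
        perm = rng.permutation(8)
        d2 = crowding_distance([front[i] for i in perm])
        assert np.allclose(d2, d[perm])


class TestTournamentSelect:
    def test_singleton_population(self, rng):
        only = ind(1.0, 1.0)
        assert tournament_select([only], 2.1, rng) is only

    def test_integer_pressure_always_picks_best(self, rng):
        best, worst = ind(0, 0), ind(1, 1)
        best.rank, worst.rank = 0, 1
        pop = [best, worst]
        # worst wins only when the best is never among the drawn candidates
        draws = [tournament_select(pop, 2.0, rng) for _ in range(500)]
        freq = np.mean([d is best for d in draws])
        assert freq == pytest.approx(0.75, abs=0.07)  # 1 - (1/2)^2

    def test_fractional_pressure_matches_analytic_frequency(self):
        rng = np.random.default_rng(0)
        best, worst = ind(0, 0), ind(1, 1)
        best.rank, worst.rank = 0, 1
        pop = [best, worst]
        pressure = 2.1
        k = math.ceil(pressure)
        p_best_mode = pressure / k
        # best drawn at least once among k: 1 - (1/2)^k; uniform branch: 1/2
        expected = p_best_mode * (1 - 0.5**k) + (1 - p_best_mode) * 0.5
        n = 10_000
        freq = np.mean([tournament_select(pop, pressure, rng) is best for _ in range(n)])
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < 3 * sigma


class TestCrossover:
    def test_zero_rate_copies(self, rng):
        a, b = ind(0, 0, genome=[0.2, 0.8]), ind(0, 0, genome=[0.6, 0.1])
        c1, c2 = crossover(a, b, 0.0, rng, BOUNDS)
        assert np.array_equal(c1.genome, a.genome)
        assert np.array_equal(c2.genome, b.genome)

    def test_identical_parents_identical_children(self, rng):
        a = ind(0, 0, genome=[0.5, 0.5])
        b = ind(0, 0, genome=[0.5, 0.5])
        c1, c2 = crossover(a, b, 1.0, rng, BOUNDS)
        assert np.array_equal(c1.genome, a.genome)
        assert np.array_equal(c2.genome, a.genome)

    def test_children_within_parent_hull(self, rng):
        for _ in range(50):
            a = ind(0, 0, genome=rng.uniform(0, 1, 2))
            b = ind(0, 0, genome=rng.uniform(0, 1, 2))
            c1, c2 = crossover(a, b, 1.0, rng)
            lo = np.minimum(a.genome, b.genome) - 1e-12
            hi = np.maximum(a.genome, b.genome) + 1e-12
            for child in (c1, c2):
                assert np.all(child.genome >= lo) and np.all(child.genome <= hi)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            crossover(ind(0, genome=[0.1]), ind(0, genome=[0.1, 0.2]), 1.0, rng)


class TestMutate:
    def test_zero_rate_unchanged(self, rng):
        a = ind(0, 0, genome=[0.3, 0.7])
        out = mutate(a, 0.0, rng, BOUNDS)
        assert np.array_equal(out.genome, a.genome)

    def test_early_childhood_rate_boost(self):
        # effective rate 0.05 * 1.30 = 0.065: verify via flip statistics
        rng = np.random.default_rng(1)
        n = 10_000
        flips = 0
        for _ in range(n):
            a = ind(0, 0, genome=[0.5])
            out = mutate(a, 0.05, rng, np.array([[0.0, 1.0]]),
                         age_group=AgeGroup.EARLY_CHILDHOOD)
            flips += int(out.genome[0] != 0.5)
        expected = 0.065
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(flips / n - expected) < 3 * sigma

    def test_base_flip_frequency_binomial(self):
        rng = np.random.default_rng(2)
        n = 10_000
        flips = sum(
            int(mutate(ind(0, genome=[0.5]), 0.05, rng, np.array([[0.0, 1.0]])).genome[0] != 0.5)
            for _ in range(n)
        )
        sigma = np.sqrt(0.05 * 0.95 / n)
        assert abs(flips / n - 0.05) < 3 * sigma

    def test_bounds_respected(self, rng):
        for _ in range(100):
            out = mutate(ind(0, 0, genome=[0.99, 0.01]), 1.0, rng, BOUNDS)
            assert np.all(out.genome >= 0.0) and np.all(out.genome <= 1.0)


class TestClonalExpand:
    def test_single_elite_exact_factor(self, rng):
        e = ind(0, 0)
        e.affinity = 1.0
        assert len(clonal_expand([e], 20, rng)) == 20

    def test_proportional_counts(self, rng):
        a, b = ind(0, 0), ind(0, 0)
        a.affinity, b.affinity = 3.0, 1.0
        clones = clonal_expand([a, b], 20, rng)
        assert len(clones) == 40
        from_a = sum(1 for c in clones if c.affinity == 3.0)
        from_b = sum(1 for c in clones if c.affinity == 1.0)
        assert (from_a, from_b) == (30, 10)

    def test_total_invariant_under_rescaling(self, rng):
        elites = []
        for aff in (0.5, 1.5, 2.0):
            e = ind(0, 0)
            e.affinity = aff
            elites.append(e)
        n1 = len(clonal_expand(elites, 7, rng))
        for e in elites:
            e.affinity *= 10.0
        n2 = len(clonal_expand(elites, 7, rng))
        assert n1 == n2 == 21

    def test_equal_affinities_uniform(self, rng):
        elites = []
        for _ in range(4):
            e = ind(0, 0)
            e.affinity = 2.0
            elites.append(e)
        clones = clonal_expand(elites, 5, rng)
        assert len(clones) == 20

    def test_every_elite_cloned_at_least_once(self, rng):
        a, b = ind(0, 0, genome=[0.0, 0.0]), ind(0, 0, genome=[1.0, 1.0])
        a.affinity, b.affinity = 100.0, 0.001
        clones = clonal_expand([a, b], 10, rng)
        assert any(np.array_equal(c.genome, b.genome) for c in clones)


class TestHypermutate:
    def test_top_affinity_untouched(self, rng):
        c = ind(0, 0, genome=[0.4, 0.6])
        out = hypermutate(c, 0.4, 1.0, rng, BOUNDS)
        assert np.array_equal(out.genome, c.genome)

    def test_inverse_affinity_scaling_monotone(self):
        rng = np.random.default_rng(3)
        n = 4000
        rates = []
        for a_norm in (0.0, 0.5, 0.9):
            flips = sum(
                int(hypermutate(ind(0, genome=[0.5]), 0.4, a_norm, rng,
                                np.array([[0.0, 1.0]])).genome[0] != 0.5)
                for _ in range(n)
            )
            rates.append(flips / n)
        assert rates[0] > rates[1] > rates[2]
        sigma = np.sqrt(0.4 * 0.6 / n)
        assert abs(rates[0] - 0.4) < 3 * sigma


class TestNegativeSelection:
    def test_empty_self_set_identity(self):
        pop = [ind(0, 0, genome=[0.5, 0.5])]
        assert negative_selection(pop, 0.85, [], BOUNDS) == pop

    def test_self_identical_individual_removed(self):
        pop = [ind(0, 0, genome=[0.5, 0.5]), ind(0, 0, genome=[0.0, 1.0])]
        kept = negative_selection(pop, 0.85, [np.array([0.5, 0.5])], BOUNDS)
        assert len(kept) == 1
        assert np.array_equal(kept[0].genome, [0.0, 1.0])

    def test_threshold_one_removes_nothing(self):
        pop = [ind(0, 0, genome=[0.5, 0.5])]
        kept = negative_selection(pop, 1.0 - 1e-12, [np.array([0.6, 0.5])], BOUNDS)
        assert len(kept) == 1


class TestRunGIO:
    def test_convex_biobjective_pareto_recovery(self):
        cfg = GIOConfig(pop_size=60, generations=40, seed=7)
        archive = run_gio(
            lambda g: (float(g[0] ** 2), float((g[0] - 2.0) ** 2)),
            [(-5.0, 5.0)],
            cfg,
        )
        xs = [m.genome[0] for m in archive.members]
        assert min(xs) >= -0.05 and max(xs) <= 2.05

    def test_elitism_single_objective_monotone(self):
        history = []

        def track(gen, pop, archive):
            history.append(min(float(i.objectives[0]) for i in pop))

        cfg = GIOConfig(pop_size=40, generations=25, seed=5)
        run_gio(
            lambda g: (float((g[0] - 1.0) ** 2), 0.0),
            [(-5.0, 5.0)],
            cfg,
            callback=track,
        )
        assert np.all(np.diff(history) <= 1e-12)

    def test_archive_mutually_nondominated_every_generation(self):
        def check(gen, pop, archive):
            objs = [m.objectives for m in archive.members]
            for a in objs:
                assert not any(dominates(b, a) for b in objs)

        cfg = GIOConfig(pop_size=30, generations=10, seed=9)
        run_gio(
            lambda g: (float(g[0] ** 2 + g[1] ** 2), float((g[0] - 1) ** 2 + g[1] ** 2)),
            [(-2.0, 2.0), (-2.0, 2.0)],
            cfg,
            callback=check,
        )

    def test_seeded_runs_identical(self):
        cfg = GIOConfig(pop_size=30, generations=8, seed=13)
        fn = lambda g: (float(g[0] ** 2), float((g[0] - 2.0) ** 2))
        a = run_gio(fn, [(-5.0, 5.0)], cfg)
        b = run_gio(fn, [(-5.0, 5.0)], cfg)
        assert len(a.members) == len(b.members)
        for x, y in zip(a.members, b.members):
            assert np.array_equal(x.genome, y.genome)
            assert np.array_equal(x.objectives, y.objectives)

    def test_non_finite_objective_reported(self):
        cfg = GIOConfig(pop_size=10, generations=2, seed=1)
        with pytest.raises(ValueError, match="non-finite"):
            run_gio(lambda g: (float("nan"), 0.0), [(0.0, 1.0)], cfg)

    def test_archive_capacity_respected(self):
        cfg = GIOConfig(pop_size=60, generations=15, pareto_size=20, seed=3)
        archive = run_gio(
            lambda g: (float(g[0] ** 2), float((g[0] - 2.0) ** 2)),
            [(-5.0, 5.0)],
            cfg,
        )
        assert len(archive.members) <= 20
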