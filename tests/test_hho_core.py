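import numpy as np
import pytest

from hawkselect import (
    KNNConfig,
    LinearMaskFitness,
    SearchConfig,
    SearchError,
    escape_energy,
    run_island,
)
from hawkselect.hho_core import (
    _copy_from_rabbit,
    exploration_one,
    exploration_two,
    generation_step,
    hard_besiege,
    hard_besiege_dive,
    init_population,
    soft_besiege,
    soft_besiege_dive,
)


def hamming(a, b):
    return int((np.asarray(a) != np.asarray(b)).sum())


def masks(rng, d=12):
    a = (rng.random(d) < 0.5).astype(np.uint8)
    b = (rng.random(d) < 0.5).astype(np.uint8)
    a[rng.integers(d)] = 1
    b[rng.integers(d)] = 1
    return a, b


class TestEscapeEnergy:
    @pytest.mark.parametrize(
        "e0,t,T,expected",
        [(0.5, 0, 500, 1.0), (0.9, 500, 500, 0.0), (-0.3, 300, 300, 0.0),
         (-0.5, 250, 500, -0.5)],
    )
    def test_schedule(self, e0, t, T, expected):
        assert escape_energy(e0, t, T) == pytest.approx(expected)

    def test_linear_decay_bounded_by_2e0(self):
        for t in range(0, 101, 10):
            assert abs(escape_energy(0.8, t, 100)) <= 2 * 0.8 + 1e-12

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            escape_energy(0.5, 0, 0)


class TestInitPopulation:
    def test_distinct_nonempty_masks_and_rabbit(self):
        cfg = SearchConfig(population_size=30, iterations=1)
        ev = LinearMaskFitness(34, seed=0)
        pop = init_population(34, cfg, np.random.default_rng(0), ev)
        keys = {h.mask.tobytes() for h in pop.hawks}
        assert len(keys) == 30
        assert all(h.n_selected >= 1 for h in pop.hawks)
        assert pop.rabbit.fitness == max(h.fitness for h in pop.hawks)
        assert pop.eval_counter == 0  # initial evaluations are not charged

    def test_same_seed_reproducible(self):
        cfg = SearchConfig(population_size=10, iterations=1)
        ev = LinearMaskFitness(16, seed=1)
        a = init_population(16, cfg, np.random.default_rng(5), ev)
        b = init_population(16, cfg, np.random.default_rng(5), ev)
        for ha, hb in zip(a.hawks, b.hawks):
            np.testing.assert_array_equal(ha.mask, hb.mask)

    def test_too_small_feature_space_errors(self):
        cfg = SearchConfig(population_size=4, iterations=1)
        with pytest.raises(SearchError):
            init_population(2, cfg, np.random.default_rng(0), LinearMaskFitness(2))


class TestOperators:
    def test_exploration_one_copies_source_bits(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            src, tgt = masks(rng)
            seed_rng = np.random.default_rng(trial)
            out = exploration_one(src, tgt, seed_rng)
            assert out.sum() >= 1
            # every changed position now carries the source's bit
            changed = np.flatnonzero(out != tgt)
            np.testing.assert_array_equal(out[changed], src[changed])
            assert hamming(tgt, out) <= -(-len(tgt) // 2)

    def test_exploration_one_identical_masks_is_identity(self):
        rng = np.random.default_rng(1)
        m = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(exploration_one(m, m.copy(), rng), m)

    def test_exploration_two_turns_on_subset_of_best(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            best, cur = masks(rng)
            out = exploration_two(best, cur, rng)
            # never clears a bit, and any new bit comes from the best mask
            assert ((out == 1) | (cur == 0)).all()
            new = np.flatnonzero((out == 1) & (cur == 0))
            assert (best[new] == 1).all()

    def test_exploration_two_superset_is_identity(self):
        rng = np.random.default_rng(3)
        best = np.array([1, 0, 0, 1], dtype=np.uint8)
        cur = np.array([1, 1, 0, 1], dtype=np.uint8)
        np.testing.assert_array_equal(exploration_two(best, cur, rng), cur)

    def test_soft_besiege_moves_toward_rabbit(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            cur, rab = masks(rng)
            out = soft_besiege(cur, rab, e=0.8, j=1.3, rng=rng)
            assert out.sum() >= 1
            if hamming(cur, rab) > 0:
                assert hamming(out, rab) <= hamming(cur, rab)
                changed = np.flatnonzero(out != cur)
                np.testing.assert_array_equal(out[changed], rab[changed])

    def test_besiege_on_identical_masks_flips_one_bit(self):
        rng = np.random.default_rng(5)
        m = np.array([1, 0, 1, 0, 1], dtype=np.uint8)
        for op in (lambda: soft_besiege(m, m.copy(), 0.7, 1.0, rng),
                   lambda: hard_besiege(m, m.copy(), rng),
                   lambda: hard_besiege_dive(m, m.copy(), rng)):
            assert hamming(op(), m) == 1

    def test_hard_besiege_reduces_hamming_by_one(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            cur, rab = masks(rng)
            k = hamming(cur, rab)
            out = hard_besiege(cur, rab, rng)
            assert out.sum() >= 1
            if k > 0:
                assert hamming(out, rab) <= k  # never backs away from the prey
            if k > 0 and cur.sum() > 1:
                assert hamming(out, rab) == k - 1

    def test_hard_besiege_dive_matches_hard_besiege_mechanics(self):
        cur = np.array([1, 1, 0, 0, 1], dtype=np.uint8)
        rab = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        a = hard_besiege(cur, rab, np.random.default_rng(7))
        b = hard_besiege_dive(cur, rab, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_soft_besiege_dive_perturbs_pure_copy_by_at_most_one_bit(self):
        d = 20
        rng = np.random.default_rng(8)
        for e in (0.5, 0.8, 1.0):
            for trial in range(30):
                cur, rab = masks(rng, d)
                m = max(1, round(abs(e) * d / 4))
                out = soft_besiege_dive(cur, rab, e, np.random.default_rng(trial))
                pure = _copy_from_rabbit(cur, rab, m, np.random.default_rng(trial))
                assert hamming(out, pure) <= 1
                assert out.sum() >= 1

    def test_soft_besiege_copy_count_grows_with_energy(self):
        # with many differing bits, the besiege step size tracks |E|
        cur = np.zeros(40, dtype=np.uint8)
        cur[0] = 1
        rab = np.ones(40, dtype=np.uint8)
        sizes = []
        for e in (0.5, 1.0, 2.0):
            moved = [hamming(soft_besiege(cur, rab, e, 1.0, np.random.default_rng(s)), cur)
                     for s in range(20)]
            sizes.append(np.mean(moved))
        assert sizes[0] <= sizes[1] <= sizes[2]


class TestGenerationStep:
    def _pop(self, n=8, d=10, seed=0):
        cfg = SearchConfig(population_size=n, iterations=10)
        ev = LinearMaskFitness(d, seed=2)
        rng = np.random.default_rng(seed)
        return init_population(d, cfg, rng, ev), cfg, ev, rng

    def test_one_candidate_per_hawk_counted(self):
        pop, cfg, ev, rng = self._pop()
        generation_step(pop, cfg, ev, rng, t=0, total=10)
        assert pop.eval_counter == 8
        generation_step(pop, cfg, ev, rng, t=1, total=10)
        assert pop.eval_counter == 16

    def test_rabbit_never_degrades_and_population_stays_unique(self):
        pop, cfg, ev, rng = self._pop(seed=3)
        for t in range(10):
            before = pop.rabbit.fitness
            generation_step(pop, cfg, ev, rng, t, 10)
            assert pop.rabbit.fitness >= before
            keys = {h.mask.tobytes() for h in pop.hawks}
            assert len(keys) == len(pop.hawks)
            assert all(h.n_selected >= 1 for h in pop.hawks)


class TestRunIsland:
    @pytest.mark.parametrize("n,t", [(2, 1), (5, 7), (10, 3), (30, 20)])
    def test_eval_counter_is_n_times_t(self, n, t):
        cfg = SearchConfig(population_size=n, iterations=t)
        pop = run_island(None, cfg, seed=1, evaluator=LinearMaskFitness(12), n_features=12)
        assert pop.eval_counter == n * t

    def test_zero_iterations_leaves_population_unevaluated(self):
        cfg = SearchConfig(population_size=5, iterations=0)
        pop = run_island(None, cfg, seed=1, evaluator=LinearMaskFitness(8), n_features=8)
        assert pop.eval_counter == 0
        assert len(pop.best_history) == 1

    def test_same_seed_bitwise_reproducible(self, small_ds):
        cfg = SearchConfig(population_size=6, iterations=8, knn=KNNConfig(k=3))
        a = run_island(small_ds, cfg, seed=21)
        b = run_island(small_ds, cfg, seed=21)
        assert a.best_history == b.best_history
        for ha, hb in zip(a.hawks, b.hawks):
            np.testing.assert_array_equal(ha.mask, hb.mask)
            assert ha.fitness == hb.fitness

    def test_best_fitness_monotone_over_generations(self, small_ds):
        cfg = SearchConfig(population_size=8, iterations=30, knn=KNNConfig(k=3))
        pop = run_island(small_ds, cfg, seed=2)
        hist = pop.best_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_all_operator_branches_exercised(self):
        cfg = SearchConfig(population_size=10, iterations=100)
        pop = run_island(None, cfg, seed=4, evaluator=LinearMaskFitness(20), n_features=20)
        assert all(v > 0 for v in pop.branch_counts.values()), pop.branch_counts

    def test_every_evaluated_mask_has_a_selected_feature(self):
        seen = []

        class Recorder:
            def __init__(self):
                self.inner = LinearMaskFitness(10)

            def __call__(self, mask):
                seen.append(int(np.asarray(mask).sum()))
                return self.inner(mask)

        cfg = SearchConfig(population_size=6, iterations=50)
        run_island(None, cfg, seed=9, evaluator=Recorder(), n_features=10)
        assert seen and min(seen) >= 1
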